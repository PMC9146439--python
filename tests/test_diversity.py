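"""Faith's PD, Bray-Curtis/ANOSIM, ANOVA and regression fits."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy import stats

from rhizostab import diversity as dv
from rhizostab import simulate as sim


def _tree(newick):
    return skbio.TreeNode.read(io.StringIO(newick))


class TestFaithPd:
    def test_star_tree_counts_tips(self):
        tree = _tree("(A:1,B:1,C:1,D:1);")
        assert dv.faith_pd(tree, {"A", "C"}) == pytest.approx(2.0)
        assert dv.faith_pd(tree, {"A", "B", "C", "D"}) == pytest.approx(4.0)

    def test_all_tips_give_total_length(self):
        tree = _tree("((A:1,B:2):0.5,(C:1.5,D:0.5):1);")
        total = sum(n.length or 0 for n in tree.traverse() if n.parent is not None)
        assert dv.faith_pd(tree, {"A", "B", "C", "D"}) == pytest.approx(total)

    def test_includes_stem_to_root(self):
        tree = _tree("((A:1,B:1):2,C:5);")
        assert dv.faith_pd(tree, {"A"}) == pytest.approx(3.0)   # 1 + stem 2
        assert dv.faith_pd(tree, {"A"}, include_root=False) == pytest.approx(0.0)
        assert dv.faith_pd(tree, {"A", "B"}, include_root=False) == pytest.approx(2.0)

    def test_matches_root_path_union_oracle_and_skbio(self):
        study_tree = sim.generate_study(sim.SimConfig(
            seed=3, n_otus_bacteria=30, n_otus_fungi=10, n_modules=2,
            module_size=5, n_indicator_otus=2)).tree
        tips = [t.name for t in study_tree.tips()]
        present = set(tips[::3])
        # oracle 1: union of root-to-tip edge sets (plus any root edge)
        edges = set()
        total = study_tree.length or 0.0
        for tip in study_tree.tips():
            if tip.name not in present:
                continue
            node = tip
            while node.parent is not None:
                if id(node) not in edges:
                    edges.add(id(node))
                    total += node.length or 0.0
                node = node.parent
        mine = dv.faith_pd(study_tree, present)
        assert mine == pytest.approx(total, abs=1e-10)
        # oracle 2: scikit-bio's implementation
        from skbio.diversity.alpha import faith_pd as skbio_faith
        counts = np.array([1 if t in present else 0 for t in tips])
        assert mine == pytest.approx(
            float(skbio_faith(counts, taxa=tips, tree=study_tree)), abs=1e-9)

    def test_monotone_in_taxon_set(self):
        tree = _tree("((A:1,B:2):0.5,(C:1.5,D:0.5):1);")
        pd_small = dv.faith_pd(tree, {"A"})
        pd_big = dv.faith_pd(tree, {"A", "D"})
        assert pd_big >= pd_small

    def test_empty_set_warns_zero_and_unknown_raises(self):
        tree = _tree("(A:1,B:1);")
        with pytest.warns(UserWarning):
            assert dv.faith_pd(tree, set()) == 0.0
        with pytest.raises(ValueError, match="not in tree"):
            dv.faith_pd(tree, {"Z"})


class TestBrayCurtisAnosim:
    def test_identical_and_disjoint_bounds(self):
        relab = pd.DataFrame({"S1": [0.5, 0.5, 0.0], "S2": [0.5, 0.5, 0.0],
                              "S3": [0.0, 0.0, 1.0]})
        d = dv.bray_curtis(relab)
        assert d.loc["S1", "S2"] == pytest.approx(0.0)
        assert d.loc["S1", "S3"] == pytest.approx(1.0)

    def test_hand_example(self):
        relab = pd.DataFrame({"u": [0.5, 0.5, 0.0], "v": [0.0, 0.5, 0.5]})
        assert dv.bray_curtis(relab).loc["u", "v"] == pytest.approx(0.5)

    def test_r_statistic_matches_skbio(self, rng):
        relab = pd.DataFrame(rng.random((10, 12)),
                             columns=[f"S{j:02d}" for j in range(12)])
        relab = relab / relab.sum(0)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=relab.columns)
        d = dv.bray_curtis(relab)
        mine = dv.anosim(d, groups, nperm=99, seed=0)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        ref = skbio.stats.distance.anosim(dm, groups.to_numpy(), permutations=0)
        assert mine.R == pytest.approx(float(ref["test statistic"]), abs=1e-12)

    def test_p_matches_exhaustive_relabelling(self, rng):
        relab = pd.DataFrame(rng.random((8, 6)), columns=[f"S{j}" for j in range(6)])
        relab = relab / relab.sum(0)
        labels = ["a", "a", "a", "b", "b", "b"]
        groups = pd.Series(labels, index=relab.columns)
        d = dv.bray_curtis(relab)
        mc = dv.anosim(d, groups, nperm=9999, seed=1)
        # exhaustive: all 20 assignments of 3 'a' labels
        D = d.to_numpy()
        iu, ju = np.triu_indices(6, k=1)
        ranks = stats.rankdata(D[iu, ju])

        def r_for(assign):
            within = np.array([assign[i] == assign[j] for i, j in zip(iu, ju)])
            m = 15
            return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

        obs = r_for(labels)
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            assign = ["b"] * 6
            for i in combo:
                assign[i] = "a"
            total += 1
            hits += r_for(assign) >= obs - 1e-12
        assert mc.p == pytest.approx(hits / total, abs=0.02)

    def test_null_r_centred_on_zero(self, rng):
        rs = []
        for _ in range(200):
            X = rng.random((5, 12))
            relab = pd.DataFrame(X / X.sum(0), columns=[f"S{j}" for j in range(12)])
            groups = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6),
                               index=relab.columns)
            rs.append(dv.anosim(dv.bray_curtis(relab), groups, nperm=1, seed=0).R)
        assert abs(np.mean(rs)) < 0.05

    def test_all_zero_distances_give_zero_r(self):
        relab = pd.DataFrame(np.tile([[0.3], [0.7]], (1, 6)),
                             columns=[f"S{j}" for j in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=relab.columns)
        res = dv.anosim(dv.bray_curtis(relab), groups, nperm=99, seed=0)
        assert res.R == 0.0 and res.p == 1.0


class TestAnova:
    def test_textbook_fixture(self):
        values = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = dv.anova_oneway(values, groups)
        assert res["F"] == pytest.approx(27.0)
        assert res["p"] == pytest.approx(float(stats.f.sf(27.0, 2, 6)))

    def test_mirrored_groups_give_zero_f(self):
        values = pd.Series([1.0, 3.0, 2.0, 1.0, 3.0, 2.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        assert dv.anova_oneway(values, groups)["F"] == pytest.approx(0.0)

    def test_matches_sums_of_squares_oracle(self, rng):
        values = pd.Series(rng.normal(size=30))
        groups = pd.Series(rng.choice(["a", "b", "c"], size=30))
        while groups.value_counts().min() < 2:
            groups = pd.Series(rng.choice(["a", "b", "c"], size=30))
        res = dv.anova_oneway(values, groups)
        grand = values.mean()
        ssb = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
                  for g in groups.unique())
        ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                  for g in groups.unique())
        G, N = groups.nunique(), len(values)
        f_ref = (ssb / (G - 1)) / (ssw / (N - G))
        assert res["F"] == pytest.approx(f_ref, abs=1e-10)


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = dv.regress(2 * x + 1, x, design="linear")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx([1.0, 2.0])

    def test_exact_parabola(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        y = 3 - 2 * x + 0.5 * x ** 2
        fit = dv.regress(y, x, design="quadratic")
        assert np.allclose(fit.predict(x), y, atol=1e-10)
        assert fit.coefficients == pytest.approx([3.0, -2.0, 0.5])

    def test_matches_pseudo_inverse_oracle(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        for design, degree in (("linear", 1), ("quadratic", 2)):
            fit = dv.regress(y, x, design=design)
            X = np.column_stack([x ** k for k in range(degree + 1)])
            beta = np.linalg.pinv(X) @ y
            assert np.allclose(fit.coefficients, beta, atol=1e-9)

    def test_quadratic_r2_at_least_linear(self, rng):
        x = rng.normal(size=20)
        y = x ** 2 + rng.normal(size=20)
        lin = dv.regress(y, x, design="linear")
        quad = dv.regress(y, x, design="quadratic")
        assert quad.r_squared >= lin.r_squared - 1e-12

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            dv.regress([1, 2, 3, 4], [2, 2, 2, 2], design="linear")
        with pytest.raises(ValueError):
            dv.regress([1, 2, 3, 4], [1, 1, 2, 2], design="quadratic")


class TestAssociationReport:
    def _meta(self, samples):
        n = len(samples)
        return pd.DataFrame({
            "group_years": np.repeat([10, 20, 30, 40], n // 4),
            "season": list(np.tile(np.repeat(["level", "wet", "dry"], n // 12), 4)),
            "transect": ["T"] * n,
        }, index=pd.Index(samples, name="sample_id"))

    def test_self_association_is_perfect(self, rng):
        samples = [f"S{j:02d}" for j in range(24)]
        meta = self._meta(samples)
        y = pd.Series(rng.normal(size=24), index=samples)
        report = dv.stability_association_report(y, {"self": y}, meta,
                                                 designs=("linear",))
        assert report["r_squared"].iloc[0] == pytest.approx(1.0)
        assert report["n"].iloc[0] == 12

    def test_shuffled_predictor_rarely_fits(self, rng):
        samples = [f"S{j:02d}" for j in range(24)]
        meta = self._meta(samples)
        y = pd.Series(rng.normal(size=24), index=samples)
        r2s = []
        for _ in range(100):
            x = pd.Series(rng.permutation(y.to_numpy()), index=samples)
            rep = dv.stability_association_report(y, {"x": x}, meta,
                                                  designs=("linear",))
            r2s.append(rep["r_squared"].iloc[0])
        assert np.median(r2s) < 0.2

    def test_missing_samples_rejected(self, rng):
        samples = [f"S{j:02d}" for j in range(24)]
        meta = self._meta(samples)
        y = pd.Series(rng.normal(size=24), index=samples)
        x = y.iloc[:20]
        with pytest.raises(ValueError, match="missing"):
            dv.stability_association_report(y, {"x": x}, meta)
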