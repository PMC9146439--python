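"""Faith's phylogenetic diversity, ANOSIM, ANOVA and the regression layer.

These are the classical community-ecology statistics that tie the
stability index to diversity and to the accumulated abundances of
indicator, core and keystone taxa. Association fits are run on group x
season mean units (12 points under the default 4-group x 3-season design)
so that one point summarises one study cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "faith_pd",
    "faith_pd_samples",
    "bray_curtis",
    "anosim",
    "AnosimResult",
    "anova_oneway",
    "regress",
    "RegressionFit",
    "stability_association_report",
]


def faith_pd(tree: skbio.TreeNode, present, include_root: bool = True) -> float:
    """Faith's PD: branch length of the minimal subtree spanning ``present`` tips.

    With ``include_root`` the stem path up to the root is counted
    (whole-tree flavour); without it only the crown subtree spanning the
    tips is summed. Empty sets score 0; unknown tips raise.
    """
    present = set(present)
    tip_names = {t.name for t in tree.tips()}
    unknown = present - tip_names
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)[:5]}")
    if not present:
        import warnings

        warnings.warn("empty taxon set; PD = 0")
        return 0.0

    total = 0.0
    # A branch is on the spanning subtree iff its subtree holds a present tip;
    # a root edge length (if the file carries one) belongs to the stem.
    counts = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            counts[id(node)] = 1 if node.name in present else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
        if counts[id(node)] > 0:
            total += node.length or 0.0
    if not include_root:
        # subtract the stem: root edge plus the path down to the MRCA
        total -= tree.length or 0.0
        node = tree
        while True:
            hot = [c for c in node.children if counts[id(c)] > 0]
            if len(hot) != 1:
                break
            node = hot[0]
            total -= node.length or 0.0
            if node.is_tip():
                break
    return total


def faith_pd_samples(tree: skbio.TreeNode, counts: pd.DataFrame,
                     include_root: bool = True) -> pd.Series:
    """Per-sample PD from a count table (presence = count > 0)."""
    values = {}
    for sample in counts.columns:
        present = counts.index[counts[sample] > 0]
        values[sample] = faith_pd(tree, present, include_root=include_root)
    return pd.Series(values, name="faith_pd")


def bray_curtis(relab: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples (columns)."""
    d = squareform(pdist(relab.T.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=relab.columns, columns=relab.columns)


@dataclass
class AnosimResult:
    R: float
    p: float
    nperm: int


def _anosim_r(ranks_cond: np.ndarray, within_cond: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    r_within = ranks_cond[within_cond].mean()
    r_between = ranks_cond[~within_cond].mean()
    return (r_between - r_within) / (m / 2.0)


def anosim(distances: pd.DataFrame, groups: pd.Series, nperm: int = 999,
           seed: int | None = None) -> AnosimResult:
    """Analysis of similarities on ranked distances with label permutation.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; p = (b+1)/(nperm+1) for permutations with R at least the
    observed.
    """
    labels = groups.reindex(distances.index).to_numpy()
    if pd.isna(labels).any():
        raise ValueError("every sample needs a group label")
    D = distances.to_numpy()
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    cond = D[iu, ju]
    if np.allclose(cond, 0.0):
        return AnosimResult(R=0.0, p=1.0, nperm=nperm)
    ranks = stats.rankdata(cond)
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nperm):
        perm = rng.permutation(labels)
        within_p = perm[iu] == perm[ju]
        if _anosim_r(ranks, within_p, n) >= r_obs - 1e-12:
            count += 1
    return AnosimResult(R=float(r_obs), p=(count + 1.0) / (nperm + 1.0), nperm=nperm)


def anova_oneway(values: pd.Series, groups: pd.Series) -> dict:
    """Classical one-way F test across groups."""
    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    arrays = [values[groups == g].to_numpy() for g in sorted(pd.unique(groups))]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance everywhere
        f, p = np.inf, 0.0
    return {"F": float(f), "p": float(p),
            "df": (len(arrays) - 1, int(sum(len(a) for a in arrays)) - len(arrays))}


@dataclass
class RegressionFit:
    design: str            # "linear" or "quadratic"
    coefficients: np.ndarray  # ascending powers: intercept, x, (x^2)
    r_squared: float
    f_stat: float
    p: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x ** k for k, c in enumerate(self.coefficients))


def regress(y, x, design: str = "linear") -> RegressionFit:
    """Least-squares polynomial fit (degree 1 or 2) with an overall F test.

    The solve runs on centred x for conditioning; coefficients are
    reported on the original scale in ascending powers.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    degree = {"linear": 1, "quadratic": 2}.get(design)
    if degree is None:
        raise ValueError(f"unknown design {design!r}")
    n = len(y)
    if n < degree + 2:
        raise ValueError(f"{design} fit needs at least {degree + 2} points")
    if len(np.unique(x)) < degree + 1:
        raise ValueError(f"{design} fit needs at least {degree + 1} distinct x values")

    mx = x.mean()
    xc = x - mx
    Xd = np.column_stack([xc ** k for k in range(degree + 1)])
    beta_c, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta_c
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    df1, df2 = degree, n - degree - 1
    if sse <= 1e-300 * max(sst, 1.0):
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((sst - sse) / df1) / (sse / df2)
        p = float(stats.f.sf(f_stat, df1, df2))

    # un-centre: expand beta_c in powers of (x - mx) back to powers of x
    if degree == 1:
        a, b = beta_c
        coef = np.array([a - b * mx, b])
    else:
        a, b, c = beta_c
        coef = np.array([a - b * mx + c * mx ** 2, b - 2 * c * mx, c])
    return RegressionFit(design=design, coefficients=coef, r_squared=float(np.clip(r2, 0, 1)),
                         f_stat=float(f_stat), p=p, n=n)


def stability_association_report(stability_per_sample: pd.Series,
                                 predictors: dict,
                                 metadata: pd.DataFrame,
                                 designs: tuple = ("linear", "quadratic")) -> pd.DataFrame:
    """Fit stability-index associations on group x season mean units.

    ``predictors`` maps association names to per-sample series (PD,
    accumulated indicator/core/keystone abundances, ...). Each series is
    averaged within (group_years, season) cells, aligned with the averaged
    stability index, and fitted with the requested designs. Direction is
    the sign of the Pearson correlation on the cell means.
    """
    samples = stability_per_sample.index
    meta = metadata.loc[list(samples)]
    keys = [meta["group_years"], meta["season"]]
    y_cells = stability_per_sample.groupby(keys, observed=True).mean()

    rows = []
    for name, series in predictors.items():
        series = pd.Series(series).reindex(samples)
        if series.isna().any():
            raise ValueError(f"predictor {name!r} missing values for some samples")
        x_cells = series.groupby(keys, observed=True).mean()
        x_cells = x_cells.reindex(y_cells.index)
        direction = np.sign(np.corrcoef(x_cells, y_cells)[0, 1]) if len(y_cells) > 2 else 0.0
        for design in designs:
            fit = regress(y_cells.to_numpy(), x_cells.to_numpy(), design=design)
            rows.append({
                "association": name,
                "design": design,
                "n": fit.n,
                "r_squared": fit.r_squared,
                "p": fit.p,
                "direction": "positive" if direction > 0 else ("negative" if direction < 0 else "flat"),
            })
    return pd.DataFrame(rows)
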