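"""Indicator species analysis, TMM normalisation and NB likelihood-ratio tests.

Indicator taxa are scored with the group-size-corrected IndVal statistic
(``IndVal.g``): for OTU i and a combination C of recovery groups,

    A = sum_{g in C} mbar_ig / sum_g mbar_ig     (specificity, group means)
    B = (# samples in C with the OTU present) / |C samples|   (fidelity)
    IndVal = sqrt(A * B)

maximised over all non-empty proper subsets of groups; significance comes
from permuting sample-to-group labels. Group means (rather than pooled
sums) keep the statistic honest under the unbalanced transect design.

Differential abundance uses a negative-binomial GLM with a log link,
per-sample offsets log(library x TMM factor), a single common dispersion
(median of per-OTU method-of-moments estimates) and a likelihood-ratio
test of one-mean-per-group against a common mean, referred to chi2(G-1).
Core taxa are the OTUs significant in both analyses.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "tmm_factors",
    "cpm",
    "indval",
    "nb_lrt",
    "select_indicators",
    "select_core_taxa",
    "bipartite_network",
]


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        warnings.warn("sample shares no positive OTU with the reference; factor set to 1")
        return 1.0
    o, r = obs[mask], ref[mask]
    p_o, p_r = o / lib_obs, r / lib_ref
    log_r = np.log2(p_o / p_r)                      # M-values
    abs_e = 0.5 * np.log2(p_o * p_r)                # A-values
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0

    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile/library-size ratio
    is closest to the mean of those ratios. The doubly trimmed (M by
    ``trim_m`` each tail, A by ``trim_a``), precision-weighted mean M-value
    against the reference gives each sample's factor.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (X > 0).sum(axis=0).min() < 1:
        raise ValueError("every sample needs at least one positive count")
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    uq = np.quantile(X, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref_idx else
        _tmm_pair(X[:, j], X[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(X.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective library sizes (library x TMM factor)."""
    lib = counts.sum(axis=0).astype(float)
    eff = lib * (factors.reindex(counts.columns) if factors is not None else 1.0)
    return counts.div(eff, axis=1) * 1e6


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

def _group_combinations(groups: list, max_combo_size: int) -> list:
    combos = []
    for k in range(1, max_combo_size + 1):
        combos.extend(itertools.combinations(range(len(groups)), k))
    return combos


def indval(abund: pd.DataFrame, groups: pd.Series, max_combo_size: int | None = None,
           nperm: int = 999, seed: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Group-size-corrected IndVal with best-combination search and permutation p.

    Parameters
    ----------
    abund : OTU x sample abundance table (counts or relative abundances).
    groups : per-sample group label, aligned to ``abund`` columns.
    max_combo_size : largest group combination searched; defaults to G-1
        (all non-empty proper subsets).
    nperm, seed : label permutations; p = (b + 1) / (nperm + 1).
    """
    groups = groups.reindex(abund.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(pd.unique(groups))
    G = len(levels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    sizes_all = groups.value_counts()
    if (sizes_all < 2).any():
        raise ValueError("every group needs at least 2 samples")
    if max_combo_size is None:
        max_combo_size = G - 1
    max_combo_size = min(max_combo_size, G - 1)

    X = abund.to_numpy(dtype=float)
    P = (X > 0).astype(float)
    H = np.stack([(groups == g).to_numpy(float) for g in levels], axis=1)  # n x G
    combos = _group_combinations(levels, max_combo_size)
    C = np.zeros((len(combos), G))
    for ci, combo in enumerate(combos):
        C[ci, list(combo)] = 1.0

    def _stats(Hm: np.ndarray):
        sizes = Hm.sum(axis=0)                      # G
        means = (X @ Hm) / sizes                    # OTU x G
        pres = P @ Hm                               # OTU x G presence counts
        total = means.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = (means @ C.T) / total               # OTU x combos
        A = np.nan_to_num(A, nan=0.0)
        n_c = sizes @ C.T                           # samples per combination
        B = (pres @ C.T) / n_c
        return np.sqrt(A * B)

    iv = _stats(H)
    best_idx = np.argmax(iv, axis=1)
    best_stat = iv[np.arange(iv.shape[0]), best_idx]

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    exceed = np.zeros(n)
    for _ in range(nperm):
        perm = rng.permutation(H.shape[0])
        perm_best = _stats(H[perm]).max(axis=1)
        exceed += perm_best >= best_stat - 1e-12
    pvals = (exceed + 1.0) / (nperm + 1.0)

    absent = X.sum(axis=1) == 0
    best_stat[absent] = 0.0
    pvals[absent] = 1.0

    combo_labels = [tuple(levels[i] for i in combos[ci]) for ci in best_idx]
    res = pd.DataFrame(
        {
            "best_combo": ["+".join(map(str, c)) for c in combo_labels],
            "combo_size": [len(c) for c in combo_labels],
            "indval": best_stat,
            "p": pvals,
            "significant": pvals < alpha,
        },
        index=abund.index,
    )
    # A and B of the best combination, for reporting
    means = (X @ H) / H.sum(axis=0)
    pres = P @ H
    total = means.sum(axis=1)
    A_col = np.zeros(n)
    B_col = np.zeros(n)
    for i, ci in enumerate(best_idx):
        sel = list(combos[ci])
        A_col[i] = means[i, sel].sum() / total[i] if total[i] > 0 else 0.0
        B_col[i] = pres[i, sel].sum() / H[:, sel].sum()
    res.insert(2, "A", A_col)
    res.insert(3, "B", B_col)
    res.index.name = "otu_id"
    return res


# ---------------------------------------------------------------------------
# Negative-binomial likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_ll_terms(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log-likelihood keeping only mu-dependent terms (r = 1/phi).

    Stable in the small-dispersion (Poisson) limit through log1p; phi = 0
    gives the exact Poisson terms y*log(mu) - mu.
    """
    pos = mu > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        logmu = np.log(mu, where=pos, out=np.zeros_like(mu, dtype=float))
    if phi == 0.0:
        yl = np.where(pos & (y > 0), y * logmu, 0.0)
        return yl - mu
    r = 1.0 / phi
    yl = np.where(pos & (y > 0), y * (logmu - np.log1p(mu / r)), 0.0)
    return yl - r * np.log1p(np.where(pos, mu, 0.0) / r)


def _fit_nb_means(Y: np.ndarray, s: np.ndarray, phi: float,
                  max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Per-OTU NB MLE of a single mean rate with offsets, by Fisher scoring.

    Y is OTU x samples, s the effective library sizes. Returns lambda per
    OTU (mu_ij = s_j * lambda_i). OTUs with zero total get lambda 0.
    """
    tot = Y.sum(axis=1)
    lam = tot / s.sum()
    active = tot > 0
    eta = np.log(np.where(active, lam, 1.0))
    for _ in range(max_iter):
        mu = np.exp(eta)[:, None] * s[None, :]
        w = 1.0 + phi * mu
        score = ((Y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = np.where(active & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        bad = np.abs(step) >= 1e-6
        if bad.any():
            warnings.warn(f"NB mean fit did not converge for {int(bad.sum())} OTU(s); "
                          "using mean of normalized counts")
            eta[bad & active] = np.log((Y / s).mean(axis=1)[bad & active])
    lam = np.where(active, np.exp(eta), 0.0)
    return lam


def _moment_dispersion(Y: np.ndarray, mu: np.ndarray, n_params: int) -> np.ndarray:
    """Per-OTU method-of-moments NB dispersion given fitted means."""
    valid = mu > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(valid, ((Y - mu) ** 2 - mu) / np.where(valid, mu ** 2, 1.0), 0.0)
    df = valid.sum(axis=1) - n_params
    phi = np.where(df > 0, contrib.sum(axis=1) / np.maximum(df, 1), np.nan)
    return phi


def nb_lrt(counts: pd.DataFrame, groups: pd.Series, factors: pd.Series | None = None,
           dispersion: float | None = None) -> pd.DataFrame:
    """Likelihood-ratio test of group-specific vs common NB means per OTU.

    Offsets are log(library size x TMM factor). ``dispersion`` overrides the
    pooled method-of-moments estimate (median over OTUs, floored at 1e-8);
    an explicit dispersion of 0 runs the exact Poisson limit.
    """
    groups = groups.reindex(counts.columns)
    levels = sorted(pd.unique(groups))
    G = len(levels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    eff = lib * (factors.reindex(counts.columns).to_numpy() if factors is not None else 1.0)
    masks = [np.asarray(groups == g) for g in levels]

    # Poisson-fit means feed the moment estimator of the common dispersion.
    if dispersion is None:
        mu0 = np.zeros_like(Y)
        for m in masks:
            lam_g = Y[:, m].sum(axis=1) / eff[m].sum()
            mu0[:, m] = lam_g[:, None] * eff[None, m]
        phis = _moment_dispersion(Y, mu0, n_params=G)
        phis = phis[np.isfinite(phis)]
        dispersion = float(np.median(phis)) if phis.size else 0.0
        dispersion = max(dispersion, 1e-8)
    dispersion = max(dispersion, 0.0)

    ll_full = np.zeros(Y.shape[0])
    for m in masks:
        lam_g = _fit_nb_means(Y[:, m], eff[m], dispersion)
        mu = lam_g[:, None] * eff[None, m]
        ll_full += _nb_ll_terms(Y[:, m], mu, dispersion).sum(axis=1)
    lam0 = _fit_nb_means(Y, eff, dispersion)
    ll_null = _nb_ll_terms(Y, lam0[:, None] * eff[None, :], dispersion).sum(axis=1)

    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    df = G - 1
    p = stats.chi2.sf(stat, df)
    res = pd.DataFrame(
        {"lrt_stat": stat, "df": df, "p": np.clip(p, np.finfo(float).tiny, 1.0),
         "dispersion": dispersion},
        index=counts.index,
    )
    res.index.name = "otu_id"
    return res


# ---------------------------------------------------------------------------
# Selection and bipartite export
# ---------------------------------------------------------------------------

def select_indicators(iv: pd.DataFrame, taxonomy: pd.DataFrame, alpha: float = 0.05,
                      bh_correct: bool = False) -> pd.DataFrame:
    """Flag significant indicators and split them by kingdom (BIs vs FIs).

    Selection is at raw p < alpha by default; ``bh_correct`` switches to
    Benjamini-Hochberg adjusted p-values as an extension. An indicator is
    *unique* to a group when its best combination is that single group.
    """
    kingdom = taxonomy["kingdom"].reindex(iv.index).fillna("other")
    out = iv.copy()
    out["kingdom"] = kingdom.to_numpy()
    pvals = out["p"].to_numpy()
    if bh_correct:
        pvals = stats.false_discovery_control(pvals, method="bh")
        out["p_adjusted"] = pvals
    out["significant"] = pvals < alpha
    out["unique_group"] = np.where(
        out["significant"] & (out["combo_size"] == 1), out["best_combo"], ""
    )
    return out


def indicator_sets(selected: pd.DataFrame) -> dict:
    """Convenience split of a :func:`select_indicators` frame into BIs/FIs."""
    sig = selected[selected["significant"]]
    return {
        "BIs": sig.index[sig["kingdom"] == "Bacteria"],
        "FIs": sig.index[sig["kingdom"] == "Fungi"],
    }


def select_core_taxa(iv: pd.DataFrame, de: pd.DataFrame, alpha: float = 0.05) -> pd.Index:
    """Core taxa: OTUs significant in both IndVal and the NB LRT."""
    common = iv.index.intersection(de.index)
    keep = (iv.loc[common, "p"] < alpha) & (de.loc[common, "p"] < alpha)
    return common[keep]


def bipartite_network(selected: pd.DataFrame, relab: pd.DataFrame | None = None):
    """Bipartite OTU-group edges for significant indicators.

    Returns ``(edges, accumulated)`` where ``edges`` has one row per
    (OTU, group) with the group drawn from the best combination, and
    ``accumulated`` (when ``relab`` is given) holds, per group, the summed
    relative abundance of that group's indicators in every sample.
    """
    sig = selected[selected["significant"]]
    rows = []
    for otu, combo in sig["best_combo"].items():
        for g in str(combo).split("+"):
            rows.append((otu, g))
    edges = pd.DataFrame(rows, columns=["otu_id", "group"])

    accumulated = None
    if relab is not None:
        groups = sorted(edges["group"].unique()) if len(edges) else []
        acc = {}
        for g in groups:
            members = edges.loc[edges["group"] == g, "otu_id"]
            acc[g] = relab.loc[relab.index.intersection(members)].sum(axis=0)
        accumulated = pd.DataFrame(acc).T
        accumulated.index.name = "group"
    return edges, accumulated
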