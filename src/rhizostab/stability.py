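"""Assemblage stability: abundance filtering, variation degree and AVD.

The average variation degree (AVD) of a sample is the mean, over retained
taxa, of the absolute standardised deviation of each taxon's relative
abundance from its mean across the replicate samples of the same group:

    a_ki = |x_ki - mu_i| / sigma_i          (sigma with n-1 denominator)
    AVD_k = (1 / m) * sum_i a_ki

A taxon that is constant within the group (sigma_i = 0) contributes no
variation and its a_ki is defined as 0. Low AVD means a stable assemblage;
the stability index reported alongside is simply -AVD, a strictly
decreasing transform that preserves every comparison between groups while
pointing "up is more stable".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "to_relative_abundance",
    "filter_by_mean_relab",
    "variation_degree",
    "avd",
    "StabilityResult",
]

#: Default mean relative-abundance retention threshold (0.001%).
DEFAULT_MIN_RELAB = 1e-5

GROUPINGS = {
    "group": ["group_years"],
    "group_season": ["group_years", "season"],
    "season": ["season"],
}


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise a count table so each sample sums to 1."""
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return counts.astype(float).div(sums, axis=1)


def filter_by_mean_relab(relab: pd.DataFrame, threshold: float = DEFAULT_MIN_RELAB) -> pd.DataFrame:
    """Keep OTUs whose mean relative abundance over all samples exceeds ``threshold``.

    The inequality is strict, so a taxon sitting exactly at the threshold is
    dropped.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = relab.mean(axis=1) > threshold
    if not keep.any():
        raise ValueError(f"no OTU exceeds mean relative abundance {threshold}")
    return relab.loc[keep]


def variation_degree(relab: pd.DataFrame, member_samples) -> pd.DataFrame:
    """Absolute standardised deviations |z| of each OTU within a sample set."""
    member_samples = list(member_samples)
    if len(member_samples) < 2:
        raise ValueError("variation degree needs at least 2 member samples")
    sub = relab[member_samples]
    mu = sub.mean(axis=1)
    sigma = sub.std(axis=1, ddof=1)
    z = sub.sub(mu, axis=0).abs()
    safe = sigma.replace(0.0, np.nan)
    z = z.div(safe, axis=0).fillna(0.0)
    return z


@dataclass
class StabilityResult:
    """Per-sample and per-group AVD with the derived stability index."""

    per_sample: pd.DataFrame  # sample_id, grouping cols, avd, stability_index
    per_group: pd.DataFrame  # grouping cols, mean_avd, mean_stability_index, n_samples
    n_otus: int
    by: str = "group"


def avd(relab: pd.DataFrame, metadata: pd.DataFrame, by: str = "group") -> StabilityResult:
    """Per-sample AVD over a table, reported within the cells of a grouping.

    Each OTU is standardised across *all* samples of the supplied table;
    a sample's AVD is the mean |z| over retained OTUs, and a group's AVD
    is the mean over its member samples. Standardising against the whole
    table (rather than within each cell) is what lets AVD rank groups by
    how far their samples scatter around the per-taxon means: the mean
    absolute within-cell z-score is scale-free and blind to noise level.
    To compare seasons within a single recovery age the caller passes the
    age-subset table, reproducing the per-cell flavour exactly.

    ``by`` is one of ``group`` (recovery age, seasons pooled),
    ``group_season`` (age x season cells) or ``season``. Every cell must
    hold at least 2 samples.
    """
    if by not in GROUPINGS:
        raise ValueError(f"unknown grouping {by!r}; expected one of {sorted(GROUPINGS)}")
    cols = GROUPINGS[by]
    missing = [s for s in relab.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    meta = metadata.loc[list(relab.columns)]

    z = variation_degree(relab, list(relab.columns))
    per_sample_avd = z.mean(axis=0)

    rows = []
    for key, cell in meta.groupby(cols, sort=True, observed=True):
        samples = list(cell.index)
        if len(samples) < 2:
            raise ValueError(f"grouping cell {key!r} has fewer than 2 samples")
        key = key if isinstance(key, tuple) else (key,)
        for s in samples:
            rows.append((s, *key, per_sample_avd[s]))

    per_sample = pd.DataFrame(rows, columns=["sample_id", *cols, "avd"]).set_index("sample_id")
    per_sample = per_sample.loc[[s for s in relab.columns]]
    per_sample["stability_index"] = -per_sample["avd"]

    per_group = (
        per_sample.groupby(cols, sort=True, observed=True)
        .agg(mean_avd=("avd", "mean"), n_samples=("avd", "size"))
        .reset_index()
    )
    per_group["mean_stability_index"] = -per_group["mean_avd"]
    return StabilityResult(per_sample=per_sample, per_group=per_group,
                           n_otus=relab.shape[0], by=by)
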