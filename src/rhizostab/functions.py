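"""Module-level functional profile aggregation.

Functional inference itself (PICRUSt2-style gene prediction, FUNGuild
guild assignment) is database-driven and out of scope; this module
performs the downstream aggregation and ranking step over any supplied
OTU -> function annotation table, weighting each function by the mean
relative abundance of the OTUs that carry it.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["read_function_table", "aggregate_module_functions"]

_FN_COLUMNS = ("otu_id", "function_id", "weight")


def read_function_table(path) -> pd.DataFrame:
    """Read an OTU -> (function, weight) annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"function table missing columns: {missing}")
    df = df[list(_FN_COLUMNS)].copy()
    df["weight"] = df["weight"].astype(float)
    if ((df["weight"] < 0) | (df["weight"] > 1)).any():
        raise ValueError("function weights must lie in [0, 1]")
    sums = df.groupby("otu_id")["weight"].sum()
    bad = sums[sums > 1 + 1e-9]
    if len(bad):
        raise ValueError(f"weights for OTU {bad.index[0]!r} sum to {bad.iloc[0]:.3f} > 1")
    return df


def aggregate_module_functions(modules: pd.Series, relab: pd.DataFrame,
                               functions: pd.DataFrame, top_k: int = 10):
    """Abundance-weighted functional profile of each module.

    The abundance of function f in module m is the sum over member OTUs of
    (mean relative abundance across samples) x (annotation weight). Returns
    ``(matrix, top)``: the full module x function matrix and a tidy frame
    flagging each module's ``top_k`` functions by abundance.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    mean_relab = relab.mean(axis=1)
    fns = functions.copy()
    fns["mean_relab"] = fns["otu_id"].map(mean_relab)
    fns["module"] = fns["otu_id"].map(modules)

    rows = []
    for mid in sorted(pd.unique(modules.dropna())):
        sub = fns[(fns["module"] == mid) & fns["mean_relab"].notna()]
        if sub.empty:
            warnings.warn(f"module {mid!r} has no annotated member with abundance data")
            continue
        contrib = (sub["mean_relab"] * sub["weight"]).groupby(sub["function_id"]).sum()
        for fid, value in contrib.items():
            rows.append((mid, fid, value))
    tidy = pd.DataFrame(rows, columns=["module", "function_id", "abundance"])
    matrix = (tidy.pivot(index="module", columns="function_id", values="abundance")
              .fillna(0.0)) if len(tidy) else pd.DataFrame()

    top_rows = []
    for mid, sub in tidy.groupby("module"):
        ranked = sub.sort_values(["abundance", "function_id"],
                                 ascending=[False, True]).head(top_k)
        for rank, (_, row) in enumerate(ranked.iterrows(), start=1):
            top_rows.append((mid, row["function_id"], row["abundance"], rank))
    top = pd.DataFrame(top_rows, columns=["module", "function_id", "abundance", "rank"])
    return matrix, top
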