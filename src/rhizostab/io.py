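"""Readers and writers for every external file the pipeline touches.

All tabular formats are tab-separated (no dialect sniffing). Count tables
are OTUs x samples with integer cells; relative abundances are always
derived internally and never read from disk, which avoids silently
normalising twice.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

__all__ = [
    "SEASONS",
    "RANKS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "write_network",
    "FLOAT_FORMAT",
]

#: Fixed season vocabulary of the sampling design (hydrological seasons).
SEASONS = ("level", "wet", "dry")

#: Taxonomic ranks recognised in QIIME-style lineage strings.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")

#: Float formatting used by every TSV writer so reruns are byte-identical.
FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """A file violated the expected on-disk contract."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise FormatError(f"duplicate {what}: {dup!r}")


def read_count_table(path) -> pd.DataFrame:
    """Read an OTU x sample count table from TSV.

    First column holds OTU ids, the header row sample ids, and every cell
    must be a non-negative integer. Row and column order are preserved.
    """
    with open(path) as fh:  # pandas mangles duplicate headers, so check first
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, f"sample id in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_count_table(df, source=str(path))


def validate_count_table(df: pd.DataFrame, source: str = "count table") -> pd.DataFrame:
    _check_unique(df.index, f"OTU id in {source}")
    _check_unique(df.columns, f"sample id in {source}")
    if df.shape[0] < 1 or df.shape[1] < 2:
        raise FormatError(f"{source}: need at least 1 OTU and 2 samples, got {df.shape}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values.astype(float)).any():
        bad = np.argwhere(~np.isfinite(df.apply(pd.to_numeric, errors="coerce").to_numpy()))
        r, c = bad[0]
        raise FormatError(
            f"{source}: non-numeric cell at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    fvalues = values.astype(float)
    bad = np.argwhere((fvalues < 0) | (fvalues != np.floor(fvalues)))
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{source}: cell must be a non-negative integer at OTU "
            f"{df.index[r]!r}, sample {df.columns[c]!r} (value {df.iat[r, c]!r})"
        )
    out = df.astype(np.int64)
    out.index.name = "otu_id"
    return out


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="otu_id")


_META_COLUMNS = ("sample_id", "group_years", "season", "transect")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample study metadata.

    Expects columns sample_id / group_years / season / transect; seasons are
    normalised case-insensitively against the fixed vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    df = df[list(_META_COLUMNS)].copy()
    _check_unique(df["sample_id"], "sample_id in metadata")
    df["season"] = df["season"].str.strip().str.lower()
    unknown = sorted(set(df["season"]) - set(SEASONS))
    if unknown:
        raise FormatError(f"unknown season label(s): {unknown}; expected one of {SEASONS}")
    try:
        df["group_years"] = df["group_years"].astype(int)
    except ValueError as exc:
        raise FormatError(f"group_years must be integer years: {exc}") from None
    if (df["group_years"] <= 0).any():
        raise FormatError("group_years must be positive")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def parse_lineage(lineage: str) -> dict:
    """Parse a QIIME-style ``k__Bacteria;p__...`` lineage into rank fields."""
    out = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        for rank, prefix in zip(RANKS, _RANK_PREFIXES):
            if token.startswith(prefix):
                name = token[len(prefix):].strip()
                if name:
                    out[rank] = name
    return out


def format_lineage(row: pd.Series) -> str:
    parts = []
    for rank, prefix in zip(RANKS, _RANK_PREFIXES):
        value = row.get(rank)
        if pd.notna(value) and value != "":
            parts.append(prefix + str(value))
    return ";".join(parts)


def read_taxonomy(path) -> pd.DataFrame:
    """Read an OTU -> lineage table into one row per OTU with rank columns.

    Kingdoms other than Bacteria/Fungi are mapped to ``other``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("taxonomy must have otu_id and lineage columns")
    df = df.rename(columns={df.columns[0]: "otu_id", df.columns[1]: "lineage"})
    _check_unique(df["otu_id"], "otu_id in taxonomy")
    parsed = pd.DataFrame([parse_lineage(s) for s in df["lineage"]], index=df["otu_id"])
    for rank in RANKS:
        if rank not in parsed.columns:
            parsed[rank] = pd.NA
    parsed = parsed[list(RANKS)]
    kingdom = parsed["kingdom"].fillna("other")
    parsed["kingdom"] = kingdom.where(kingdom.isin(["Bacteria", "Fungi"]), "other")
    parsed.index.name = "otu_id"
    return parsed


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    lineage = taxonomy.apply(format_lineage, axis=1)
    pd.DataFrame({"otu_id": taxonomy.index, "lineage": lineage.values}).to_csv(
        path, sep="\t", index=False
    )


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted Newick tree; tip labels are OTU ids."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"unparseable Newick file {path}: {exc}") from None
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip label in tree")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.graph


def write_network(net, path_prefix) -> list:
    """Write a co-occurrence network as GraphML plus edge and node TSVs.

    Returns the list of paths written. Node and edge rows are sorted so the
    files are reproducible byte for byte.
    """
    g = _as_graph(net)
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = [
        prefix.with_suffix(".graphml"),
        Path(str(prefix) + "_edges.tsv"),
        Path(str(prefix) + "_nodes.tsv"),
    ]

    out = nx.Graph()
    for node in sorted(g.nodes):
        attrs = {k: v for k, v in g.nodes[node].items() if v is not None}
        out.add_node(node, **attrs)
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    nx.write_graphml(out, paths[0])

    edges = pd.DataFrame(
        [(u, v, g.edges[u, v].get("spearman_rho", g.edges[u, v].get("weight")))
         for u, v in sorted(tuple(sorted(e)) for e in g.edges)],
        columns=["source", "target", "spearman_rho"],
    )
    edges.to_csv(paths[1], sep="\t", index=False, float_format=FLOAT_FORMAT)

    nodes = pd.DataFrame(
        [
            (
                n,
                g.nodes[n].get("kingdom", ""),
                g.degree[n],
                g.nodes[n].get("module", ""),
                bool(g.nodes[n].get("keystone", False)),
            )
            for n in sorted(g.nodes)
        ],
        columns=["otu", "kingdom", "degree", "module", "keystone"],
    )
    nodes.to_csv(paths[2], sep="\t", index=False)
    return paths


def read_network(path_prefix) -> nx.Graph:
    """Read back a network written by :func:`write_network` (GraphML part)."""
    return nx.read_graphml(Path(path_prefix).with_suffix(".graphml"))
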