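"""Positive Spearman co-occurrence networks, modules and keystone taxa.

Edges connect OTU pairs whose Spearman rank correlation across samples
exceeds the r threshold with a two-sided p below the p threshold (both
strict); only positive correlations are kept. Modules come from greedy
modularity maximisation (Clauset-Newman-Moore agglomeration) on the
unweighted thresholded graph, and keystone taxa are the nodes in the top
1% of degree, a floor(fraction x n)-sized set with a documented tie-break.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats

__all__ = [
    "CooccurrenceNetwork",
    "spearman_correlations",
    "spearman_network",
    "greedy_modularity",
    "keystone_species",
    "module_abundance",
    "network_stats",
]


@dataclass
class CooccurrenceNetwork:
    """Thresholded co-occurrence graph plus module/keystone annotations."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    modularity: float | None = None

    @property
    def modules(self) -> pd.Series:
        data = nx.get_node_attributes(self.graph, "module")
        return pd.Series(data, name="module").sort_index()

    @property
    def keystones(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("keystone"))

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree), name="degree").sort_index()


def spearman_correlations(table: pd.DataFrame):
    """Full Spearman rho and two-sided p matrices between all OTU pairs.

    Uses average ranks for ties and the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom. Constant
    OTUs have undefined correlations; they are returned as NaN and reported
    with a single warning.
    """
    X = table.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples for co-occurrence correlations")
    ranks = stats.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant OTU(s) have undefined correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return (pd.DataFrame(rho, index=table.index, columns=table.index),
            pd.DataFrame(p, index=table.index, columns=table.index))


def spearman_network(table: pd.DataFrame, taxonomy: pd.DataFrame | None = None,
                     r_threshold: float = 0.7, p_threshold: float = 0.001,
                     positive_only: bool = True) -> CooccurrenceNetwork:
    """Build the thresholded co-occurrence graph from a normalised table.

    Nodes are the OTUs incident to at least one retained edge; edge weights
    store the Spearman rho.
    """
    rho, p = spearman_correlations(table)
    R = rho.to_numpy()
    P = p.to_numpy()
    iu, ju = np.triu_indices(R.shape[0], k=1)
    with np.errstate(invalid="ignore"):
        keep = (P[iu, ju] < p_threshold) & ~np.isnan(R[iu, ju])
        if positive_only:
            keep &= R[iu, ju] > r_threshold
        else:
            keep &= np.abs(R[iu, ju]) > r_threshold
    g = nx.Graph()
    otus = table.index.to_numpy()
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(otus[i], otus[j], spearman_rho=float(R[i, j]), weight=float(R[i, j]))
    if taxonomy is not None:
        kingdom = taxonomy["kingdom"]
        for node in g.nodes:
            g.nodes[node]["kingdom"] = str(kingdom.get(node, "other"))
    return CooccurrenceNetwork(graph=g, r_threshold=r_threshold, p_threshold=p_threshold)


def greedy_modularity(net: CooccurrenceNetwork,
                      weighted: bool = False) -> tuple[pd.Series, float]:
    """Assign modules by CNM greedy modularity maximisation; returns (modules, Q).

    The thresholded graph is treated as unweighted by default (edges are
    near-binary after the rho cutoff); ``weighted`` switches both the
    maximisation and the reported Q to the stored correlation weights.
    Module ids are integers starting at 1, ordered by decreasing module
    size with ties broken by the lexicographically smallest member, so the
    labelling is reproducible run to run.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges; modular structure undefined")
    weight = "weight" if weighted else None
    comms = nx_community.greedy_modularity_communities(g, weight=weight)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    modules = {}
    for mid, members in enumerate(comms, start=1):
        for node in members:
            modules[node] = mid
    q = nx_community.modularity(g, [set(c) for c in comms], weight=weight)
    nx.set_node_attributes(g, modules, "module")
    net.modularity = float(q)
    return pd.Series(modules, name="module").sort_index(), float(q)


def keystone_species(net: CooccurrenceNetwork, fraction: float = 0.01,
                     abundance: pd.Series | None = None) -> list:
    """Keystone taxa: the top ``fraction`` of nodes by degree.

    k = max(1, floor(fraction * n)). Ties at the cutoff are broken by
    higher total abundance (when provided), then lexicographic OTU id.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        return []
    k = max(1, math.floor(fraction * n))
    ab = abundance if abundance is not None else pd.Series(dtype=float)

    def sort_key(node):
        return (-g.degree[node], -float(ab.get(node, 0.0)), node)

    ranked = sorted(g.nodes, key=sort_key)
    chosen = ranked[:k]
    nx.set_node_attributes(g, False, "keystone")
    for node in chosen:
        g.nodes[node]["keystone"] = True
    return sorted(chosen)


@dataclass
class ModuleSummary:
    """Per-module core-taxa abundance series and composition bookkeeping."""

    per_sample: pd.DataFrame    # modules x samples, accumulated core relab
    per_group: pd.DataFrame     # modules x groups, mean over member samples
    composition: pd.DataFrame   # module, kingdom, n_members, n_core
    top_modules: list = field(default_factory=list)


def module_abundance(net: CooccurrenceNetwork, core: pd.Index | set,
                     relab: pd.DataFrame, metadata: pd.DataFrame,
                     top_k: int = 4) -> ModuleSummary:
    """Accumulated relative abundance of each module's core taxa per sample.

    A module with no core members keeps a zero series. ``top_modules``
    ranks modules by overall mean accumulated core abundance (top ``top_k``).
    """
    modules = net.modules
    if modules.empty:
        raise ValueError("modules not assigned; run greedy_modularity first")
    core = pd.Index(core)
    samples = relab.columns
    rows = {}
    comp_rows = []
    for mid in sorted(modules.unique()):
        members = modules.index[modules == mid]
        core_members = members.intersection(core).intersection(relab.index)
        series = (relab.loc[core_members].sum(axis=0)
                  if len(core_members) else pd.Series(0.0, index=samples))
        rows[mid] = series
        for kingdom in ("Bacteria", "Fungi", "other"):
            n_k = sum(1 for m in members
                      if net.graph.nodes[m].get("kingdom", "other") == kingdom)
            if n_k:
                comp_rows.append((mid, kingdom, n_k,
                                  sum(1 for m in core_members
                                      if net.graph.nodes[m].get("kingdom", "other") == kingdom)))
    per_sample = pd.DataFrame(rows).T
    per_sample.index.name = "module"
    meta = metadata.loc[list(samples)]
    per_group = per_sample.T.groupby(meta["group_years"]).mean().T
    order = per_sample.mean(axis=1).sort_values(ascending=False)
    top = list(order.index[:top_k])
    composition = pd.DataFrame(comp_rows, columns=["module", "kingdom", "n_members", "n_core"])
    return ModuleSummary(per_sample=per_sample, per_group=per_group,
                         composition=composition, top_modules=top)


def network_stats(net: CooccurrenceNetwork) -> dict:
    """Topology summary: node/edge counts, mean degree, density, histogram."""
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    degs = [d for _, d in g.degree]
    by_kingdom = {}
    for node, data in g.nodes(data=True):
        kingdom = data.get("kingdom", "other")
        by_kingdom[kingdom] = by_kingdom.get(kingdom, 0) + 1
    return {
        "n_nodes": n,
        "n_edges": m,
        "mean_degree": (2.0 * m / n) if n else 0.0,
        "density": nx.density(g),
        "degree_histogram": nx.degree_histogram(g),
        "max_degree": max(degs) if degs else 0,
        "nodes_by_kingdom": by_kingdom,
    }
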