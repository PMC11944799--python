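"""Spearman-thresholded co-occurrence networks and their topology.

Edges are OTU pairs whose Spearman correlation across samples satisfies
|r| > r_min (default 0.60) and p < alpha (default 0.05, raw p-values by
default). Edge weight is |r| with the sign stored separately; isolated
nodes are dropped, so node counts refer to connected nodes only. Topology
metrics follow the conventions of Gephi-style network summaries; community
structure is Louvain on |r| weights; robustness is the mean relative size
of the largest connected component after random removal of a fixed
fraction of nodes.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.stats as sps

from .tables import OTUTable

__all__ = [
    "NetworkConfig",
    "CooccurrenceNetwork",
    "TopologySummary",
    "spearman_matrix",
    "build_network",
    "topology_summary",
    "robustness",
    "detect_modules",
    "average_degree_from_counts",
    "density_from_counts",
]


# ---------------------------------------------------------------------------
# Closed-form identities (degree and density from printed counts)
# ---------------------------------------------------------------------------

def average_degree_from_counts(node_num: int, edge_num: int) -> float:
    """Average degree 2E/N of an undirected simple graph."""
    if node_num <= 0:
        raise ValueError("node_num must be positive")
    return 2.0 * edge_num / node_num


def density_from_counts(node_num: int, edge_num: int) -> float:
    """Density 2E/(N(N-1)) = average_degree/(N-1)."""
    if node_num <= 1:
        raise ValueError("density needs at least two nodes")
    return 2.0 * edge_num / (node_num * (node_num - 1))


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Thresholds for network construction."""

    keep_fraction: float = 0.8
    r_min: float = 0.60
    alpha: float = 0.05
    p_adjust: str = "none"  # {"none", "BH"}

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.p_adjust not in ("none", "BH"):
            raise ValueError("p_adjust must be 'none' or 'BH'")


@dataclass
class CooccurrenceNetwork:
    """Undirected signed weighted graph of OTU nodes.

    ``edges`` holds ``(otu_a, otu_b, r, p)`` tuples with ``otu_a < otu_b``;
    ``modules`` maps node -> community id (filled by :func:`detect_modules`).
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]
    modules: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, nodes, edges, modules=None) -> "CooccurrenceNetwork":
        canon = [
            (a, b, float(r), float(p)) if str(a) < str(b) else (b, a, float(r), float(p))
            for a, b, r, p in edges
        ]
        canon.sort(key=lambda e: (e[0], e[1]))
        return cls(nodes=[str(n) for n in nodes], edges=canon, modules=dict(modules or {}))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for a, b, _, _ in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph()
        g.add_vertices(self.n_nodes)
        g.vs["name"] = list(self.nodes)
        index = {n: i for i, n in enumerate(self.nodes)}
        g.add_edges([(index[a], index[b]) for a, b, _, _ in self.edges])
        g.es["r"] = [r for _, _, r, _ in self.edges]
        g.es["weight"] = [abs(r) for _, _, r, _ in self.edges]
        return g


@dataclass
class TopologySummary:
    """The seventeen topology metrics reported per network."""

    average_degree: float
    average_weighted_degree: float
    diameter: float
    average_path_length: float
    density: float
    modularity: float
    n_communities: int
    average_clustering_coefficient: float
    node_num: int
    edge_num: int
    transitivity: float
    assortativity: float
    degree_centralization: float
    average_neighbors: float
    frac_positive: float
    frac_negative: float
    robustness: float

    def as_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (int, np.integer)):
                out[k] = int(v)
            else:
                out[k] = None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        return out


# ---------------------------------------------------------------------------
# Correlation matrix and construction
# ---------------------------------------------------------------------------

def spearman_matrix(table: OTUTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlations between OTUs across samples.

    Average-rank tie handling; two-sided p from the t approximation.
    Constant OTU columns yield missing r/p for their pairs with a warning.
    """
    counts = table.counts.to_numpy(dtype=float)
    n, m = counts.shape
    if n < 4:
        raise ValueError("need at least four samples for Spearman correlations")
    ranks = sps.rankdata(counts, axis=0)
    constant = np.ptp(counts, axis=0) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant OTU column(s); r set missing")
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    norms[constant] = np.nan
    r = (centered.T @ centered) / np.outer(norms, norms)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)
    ids = table.otu_ids
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a flat vector."""
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    cummin = 1.0
    for rank_idx in range(m - 1, -1, -1):
        idx = order[rank_idx]
        cummin = min(cummin, p[idx] * m / (rank_idx + 1))
        adjusted[idx] = cummin
    return adjusted


def build_network(
    r: pd.DataFrame, p: pd.DataFrame, cfg: NetworkConfig | None = None
) -> CooccurrenceNetwork:
    """Threshold the correlation matrices into a co-occurrence network.

    Keeps pairs with |r| strictly above ``cfg.r_min`` and p strictly below
    ``cfg.alpha`` (optionally BH-adjusted); drops isolated nodes.
    """
    cfg = cfg or NetworkConfig()
    if r.shape != p.shape or list(r.index) != list(p.index):
        raise ValueError("r and p matrices do not match")
    ids = [str(i) for i in r.index]
    rv = r.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float).copy()
    iu = np.triu_indices(len(ids), k=1)
    if cfg.p_adjust == "BH":
        flat = pv[iu]
        ok = ~np.isnan(flat)
        flat_adj = flat.copy()
        flat_adj[ok] = _bh_adjust(flat[ok])
        pv[iu] = flat_adj
        pv.T[iu] = flat_adj
    with np.errstate(invalid="ignore"):
        keep = (np.abs(rv[iu]) > cfg.r_min) & (pv[iu] < cfg.alpha)
    keep &= ~np.isnan(rv[iu])
    rows, cols = iu[0][keep], iu[1][keep]
    edges = [
        (ids[i], ids[j], float(rv[i, j]), float(pv[i, j]))
        for i, j in zip(rows, cols)
    ]
    if not edges:
        warnings.warn("no correlations pass the thresholds; network is empty")
        return CooccurrenceNetwork.from_edges(nodes=[], edges=[])
    connected = sorted({n for a, b, _, _ in edges for n in (a, b)})
    return CooccurrenceNetwork.from_edges(nodes=connected, edges=edges)


# ---------------------------------------------------------------------------
# Communities, robustness, topology
# ---------------------------------------------------------------------------

def detect_modules(net: CooccurrenceNetwork, seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain partition on |r| weights; returns (node -> module, modularity Q).

    python-igraph draws from Python's global ``random`` module, so the seed
    is applied there (and the previous RNG state restored afterwards).
    """
    if net.n_edges == 0:
        raise ValueError("cannot detect modules in an empty network")
    g = net.to_igraph()
    state = _random.getstate()
    try:
        _random.seed(seed)
        clustering = g.community_multilevel(weights="weight")
    finally:
        _random.setstate(state)
    membership = {net.nodes[i]: int(m) for i, m in enumerate(clustering.membership)}
    q = float(g.modularity(clustering.membership, weights="weight"))
    net.modules = membership
    return membership, q


def robustness(
    net: CooccurrenceNetwork,
    removal_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int = 0,
) -> float:
    """Attack tolerance: mean relative size of the largest connected component
    after uniformly removing ``floor(removal_fraction * N)`` nodes.

    The mean is over ``n_reps`` seeded removal draws; the denominator is the
    original node count.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    n = net.n_nodes
    if n < 2:
        raise ValueError("robustness needs at least two nodes")
    g = net.to_igraph()
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    sizes = []
    for _ in range(n_reps):
        removed = rng.choice(n, size=n_remove, replace=False)
        sub = g.copy()
        sub.delete_vertices(removed.tolist())
        if sub.vcount() == 0:
            sizes.append(0)
        else:
            sizes.append(max(sub.connected_components().sizes()))
    return float(np.mean(sizes) / n)


def topology_summary(net: CooccurrenceNetwork, seed: int = 0) -> TopologySummary:
    """Compute the full 17-metric topology summary of a network.

    Path-based and clustering metrics are reported missing (NaN) for
    networks with fewer than three nodes; path metrics are computed on the
    largest connected component with unweighted shortest paths.
    """
    n, e = net.n_nodes, net.n_edges
    if n < 1:
        raise ValueError("empty network has no topology")
    g = net.to_igraph()
    degrees = np.array(g.degree())

    average_degree = average_degree_from_counts(n, e)
    weighted = np.zeros(n)
    index = {node: i for i, node in enumerate(net.nodes)}
    for a, b, r, _ in net.edges:
        weighted[index[a]] += abs(r)
        weighted[index[b]] += abs(r)
    average_weighted_degree = float(weighted.mean())
    density = density_from_counts(n, e) if n > 1 else np.nan

    if n >= 3 and e >= 1:
        comps = g.connected_components()
        lcc = comps.giant()
        diameter = float(lcc.diameter(unconn=False))
        average_path_length = float(lcc.average_path_length(unconn=False))
        average_clustering = float(
            np.mean(g.transitivity_local_undirected(mode="zero"))
        )
        transitivity = float(g.transitivity_undirected(mode="zero"))
        assortativity = float(g.assortativity_degree(directed=False))
        knn, _ = g.knn()
        average_neighbors = float(np.mean(knn))
    else:
        diameter = average_path_length = np.nan
        average_clustering = transitivity = assortativity = np.nan
        average_neighbors = np.nan

    if n > 2:
        centralization = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
    else:
        centralization = np.nan

    if e >= 1:
        _, modularity = detect_modules(net, seed=seed)
        n_communities = len(set(net.modules.values()))
        signs = np.array([r for _, _, r, _ in net.edges])
        frac_positive = float((signs > 0).mean())
        frac_negative = float((signs < 0).mean())
    else:
        modularity, n_communities = np.nan, 0
        frac_positive = frac_negative = np.nan

    robust = robustness(net, seed=seed) if n >= 2 else np.nan

    return TopologySummary(
        average_degree=average_degree,
        average_weighted_degree=average_weighted_degree,
        diameter=diameter,
        average_path_length=average_path_length,
        density=density,
        modularity=modularity,
        n_communities=n_communities,
        average_clustering_coefficient=average_clustering,
        node_num=n,
        edge_num=e,
        transitivity=transitivity,
        assortativity=assortativity,
        degree_centralization=centralization,
        average_neighbors=average_neighbors,
        frac_positive=frac_positive,
        frac_negative=frac_negative,
        robustness=robust,
    )
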