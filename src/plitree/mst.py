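"""Strongest-connection spanning tree and its global topology metrics.

On similarity weights (PLI in [0, 1]) the backbone of interest is the
*maximum*-weight spanning tree — identical to the minimum spanning tree of
the distances ``1 - w`` — built here with Kruskal's algorithm under a
deterministic tie-break.

Seven global metrics summarize tree shape. With ``N`` nodes and
``M = N - 1`` edges:

==================  =====================================================
degree              max node degree / M
leaf fraction       number of degree-1 nodes / M
diameter            longest hop distance between any two nodes / M
eccentricity        mean over nodes of the longest hop distance / M
BC                  max normalized betweenness centrality, in [0, 1]
tree hierarchy      N_leaf / (2 * M * BC_max)
kappa               <degree^2> / <degree>  (degree divergence)
==================  =====================================================

High leaf fraction / kappa and low diameter / eccentricity indicate a
star-like, hub-integrated tree; the opposite pattern a path-like one.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "SpanningTree",
    "MetricRecord",
    "METRIC_NAMES",
    "build_tree",
    "degree_norm",
    "leaf_fraction",
    "diameter_norm",
    "eccentricity_norm",
    "bc_max",
    "tree_hierarchy",
    "kappa",
    "metric_record",
]


@dataclass
class SpanningTree:
    """An N-node, (N-1)-edge connected acyclic backbone with edge weights."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    labels: list[str]

    def __post_init__(self) -> None:
        n = self.n_nodes
        if len(self.edges) != n - 1:
            raise ValueError(f"tree on {n} nodes must have {n - 1} edges")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} nodes")
        g = self.to_networkx()
        if g.number_of_nodes() != n or not nx.is_connected(g):
            raise ValueError("edges do not form a connected spanning tree")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class MetricRecord:
    """The seven tree metrics plus mean PLI for one subject x band."""

    degree_norm: float
    leaf_fraction: float
    diameter_norm: float
    eccentricity_norm: float
    bc_max: float
    tree_hierarchy: float
    kappa: float
    mean_pli: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pli": self.mean_pli,
            "degree": self.degree_norm,
            "eccentricity": self.eccentricity_norm,
            "bc": self.bc_max,
            "kappa": self.kappa,
            "diameter": self.diameter_norm,
            "leaf_fraction": self.leaf_fraction,
            "tree_hierarchy": self.tree_hierarchy,
        }


#: Canonical metric order for output tables.
METRIC_NAMES: tuple[str, ...] = (
    "pli",
    "degree",
    "eccentricity",
    "bc",
    "kappa",
    "diameter",
    "leaf_fraction",
    "tree_hierarchy",
)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def build_tree(m: ConnectivityMatrix) -> SpanningTree:
    """Maximum-weight spanning tree of the complete weighted graph.

    Kruskal on edges sorted by (descending weight, ascending node-index
    pair), so the result is deterministic even under weight ties.
    """
    n = m.n_channels
    if n < 2:
        raise ValueError(f"need >= 2 nodes, got {n}")
    iu, ju = np.triu_indices(n, k=1)
    w = m.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    return SpanningTree(n, edges, list(m.labels))


def degree_norm(t: SpanningTree) -> float:
    """Maximum node degree divided by M = N - 1."""
    return float(t.degrees().max()) / (t.n_nodes - 1)


def leaf_fraction(t: SpanningTree) -> float:
    """Fraction of tree nodes with degree 1, relative to M = N - 1."""
    return float((t.degrees() == 1).sum()) / (t.n_nodes - 1)


def diameter_norm(t: SpanningTree) -> float:
    """Longest hop distance between any node pair, divided by M."""
    return nx.diameter(t.to_networkx()) / (t.n_nodes - 1)


def eccentricity_norm(t: SpanningTree) -> float:
    """Mean over nodes of the longest hop distance to any other node, / M."""
    ecc = nx.eccentricity(t.to_networkx())
    return float(np.mean(list(ecc.values()))) / (t.n_nodes - 1)


def bc_max(t: SpanningTree) -> float:
    """Maximum normalized betweenness centrality over nodes.

    Per-node BC counts, over ordered pairs (j, k) with j != k and both
    different from i, the fraction of shortest j-k paths through i (each
    pair has exactly one path in a tree), normalized by (n-1)(n-2).
    Requires N >= 3.
    """
    if t.n_nodes < 3:
        raise ValueError("betweenness centrality needs >= 3 nodes")
    bc = nx.betweenness_centrality(t.to_networkx(), normalized=True)
    return float(max(bc.values()))


def tree_hierarchy(t: SpanningTree) -> float:
    """T_H = N_leaf / (2 * M * BC_max).

    Balances integration (many leaves) against hub overload (high BC_max).
    """
    n_leaf = int((t.degrees() == 1).sum())
    b = bc_max(t)
    if b == 0:
        raise ValueError("tree hierarchy undefined for BC_max = 0")
    return n_leaf / (2 * (t.n_nodes - 1) * b)


def kappa(t: SpanningTree) -> float:
    """Degree divergence: mean squared degree over mean degree."""
    deg = t.degrees().astype(float)
    return float((deg**2).mean() / deg.mean())


def metric_record(trees: list[SpanningTree], mean_pli: float) -> MetricRecord:
    """Per-tree metrics averaged over a subject's epoch-level trees."""
    if not trees:
        raise ValueError("need at least one tree")
    n = trees[0].n_nodes
    for t in trees[1:]:
        if t.n_nodes != n:
            raise ValueError("trees differ in size")
    return MetricRecord(
        degree_norm=float(np.mean([degree_norm(t) for t in trees])),
        leaf_fraction=float(np.mean([leaf_fraction(t) for t in trees])),
        diameter_norm=float(np.mean([diameter_norm(t) for t in trees])),
        eccentricity_norm=float(np.mean([eccentricity_norm(t) for t in trees])),
        bc_max=float(np.mean([bc_max(t) for t in trees])),
        tree_hierarchy=float(np.mean([tree_hierarchy(t) for t in trees])),
        kappa=float(np.mean([kappa(t) for t in trees])),
        mean_pli=float(mean_pli),
    )
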