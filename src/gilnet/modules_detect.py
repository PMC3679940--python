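"""Module detection: Markov clustering and link-community detection.

MCL simulates flow on the graph by alternating matrix expansion (squaring)
and inflation (entrywise powers with column renormalization) until the
matrix is idempotent; clusters are the connected components of the
attractor support and form a partition of the nodes.

Link communities cluster *edges*: edges sharing an endpoint are scored by
the Jaccard similarity of the inclusive neighborhoods of their outer nodes,
single-linkage merged, and the dendrogram is cut where the partition
density D is maximal.  Genes may then belong to several modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network_build import CoexpressionNetwork

__all__ = [
    "ModuleSet",
    "LinkCommunityResult",
    "mcl",
    "link_communities",
    "partition_density",
    "module_size_stats",
]


@dataclass
class ModuleSet:
    method: str  # "mcl" | "lcm"
    modules: dict[str, frozenset[str]] = field(default_factory=dict)
    edge_modules: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)

    def sizes(self) -> list[int]:
        return [len(g) for g in self.modules.values()]

    def covered_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.modules.values():
            out |= genes
        return out


@dataclass
class LinkCommunityResult:
    module_set: ModuleSet
    partition_density: float
    cut_height: float
    dendrogram: list[tuple[float, int, int, int]]
    # (height, community_a, community_b, merged_id) in merge order


def mcl(
    net: CoexpressionNetwork,
    inflation: float = 2.0,
    pruning: float = 1e-5,
    max_iter: int = 100,
    weighted: bool = True,
) -> ModuleSet:
    """Markov clustering of a network into a node partition."""
    nodes = net.nodes
    if not nodes:
        raise ValueError("cannot cluster an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, r in net.edges:
        w = abs(r) if weighted else 1.0
        M[index[a], index[b]] = w
        M[index[b], index[a]] = w
    np.fill_diagonal(M, 1.0)  # self-loops stabilize the iteration
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded ** inflation
        inflated[inflated < pruning] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - M).max() < 1e-8:
            M = inflated
            converged = True
            break
        M = inflated
    if not converged:
        warnings.warn("MCL did not reach idempotence; clustering current support",
                      stacklevel=2)

    # clusters = connected components of the attractor support
    support = (M > 0) | (M.T > 0)
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = next_label
        while stack:
            v = stack.pop()
            for u in np.flatnonzero(support[v]):
                if labels[u] < 0:
                    labels[u] = next_label
                    stack.append(u)
        next_label += 1
    modules = {
        f"mcl{lab:04d}": frozenset(nodes[i] for i in np.flatnonzero(labels == lab))
        for lab in range(next_label)
    }
    return ModuleSet("mcl", modules)


def partition_density(
    edge_communities: list[frozenset[tuple[str, str]]], n_edges_total: int
) -> float:
    """D = (2/M) * sum_c m_c (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)).

    Communities whose node count ``n_c`` is <= 2 contribute 0.
    """
    if n_edges_total == 0:
        return 0.0
    total = 0.0
    for community in edge_communities:
        m_c = len(community)
        nodes: set[str] = set()
        for a, b in community:
            nodes.add(a)
            nodes.add(b)
        n_c = len(nodes)
        if n_c <= 2:
            continue
        total += m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / n_edges_total


class _EdgeUnionFind:
    """Union-find over edges tracking per-community edge and node counts."""

    def __init__(self, edges: list[tuple[str, str]]):
        self.parent = list(range(len(edges)))
        self.m = [1] * len(edges)
        self.node_count: list[dict[str, int]] = [
            {a: 1, b: 1} for a, b in edges
        ]
        # running sum of per-community partition-density terms
        self.term = [0.0] * len(edges)
        self.term_sum = 0.0

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    @staticmethod
    def _term(m_c: int, n_c: int) -> float:
        if n_c <= 2:
            return 0.0
        return m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))

    def union(self, i: int, j: int) -> tuple[int, int] | None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return None
        if len(self.node_count[ri]) < len(self.node_count[rj]):
            ri, rj = rj, ri
        self.term_sum -= self.term[ri] + self.term[rj]
        self.parent[rj] = ri
        self.m[ri] += self.m[rj]
        counts = self.node_count[ri]
        for node, c in self.node_count[rj].items():
            counts[node] = counts.get(node, 0) + c
        self.term[ri] = self._term(self.m[ri], len(counts))
        self.term_sum += self.term[ri]
        return ri, rj


def _edge_pair_similarities(
    edges: list[tuple[str, str]]
) -> list[tuple[float, int, int]]:
    """(1 - S, i, j) for all edge pairs sharing a node.

    For edges (i, k) and (j, k), S is the Jaccard similarity of the
    inclusive neighborhoods of i and j.
    """
    neighbors: dict[str, set[str]] = {}
    incident: dict[str, list[int]] = {}
    for idx, (a, b) in enumerate(edges):
        neighbors.setdefault(a, {a}).add(b)
        neighbors.setdefault(b, {b}).add(a)
        incident.setdefault(a, []).append(idx)
        incident.setdefault(b, []).append(idx)
    out: list[tuple[float, int, int]] = []
    for k, edge_ids in incident.items():
        for x in range(len(edge_ids)):
            for y in range(x + 1, len(edge_ids)):
                e, f = edge_ids[x], edge_ids[y]
                a = edges[e][0] if edges[e][1] == k else edges[e][1]
                b = edges[f][0] if edges[f][1] == k else edges[f][1]
                na, nb = neighbors[a], neighbors[b]
                s = len(na & nb) / len(na | nb)
                out.append((1.0 - s, min(e, f), max(e, f)))
    return out


def link_communities(net: CoexpressionNetwork) -> LinkCommunityResult:
    """Single-linkage clustering of edges cut at maximum partition density.

    Ties in D are broken toward the lower cut height.  The edge communities
    partition the edge set; gene modules are the node sets of communities
    with at least 2 edges (single-edge communities stay in the edge
    partition but are not reported as modules).
    """
    edges = [(a, b) for a, b, _ in net.edges]
    if not edges:
        raise ValueError("cannot cluster an empty network")
    m_total = len(edges)
    pairs = sorted(set(_edge_pair_similarities(edges)))

    uf = _EdgeUnionFind(edges)
    best_d, best_height = 0.0, 0.0
    dendrogram: list[tuple[float, int, int, int]] = []
    i = 0
    while i < len(pairs):
        height = pairs[i][0]
        while i < len(pairs) and pairs[i][0] == height:
            _, e, f = pairs[i]
            merged = uf.union(e, f)
            if merged is not None:
                dendrogram.append((height, merged[1], merged[0], merged[0]))
            i += 1
        d = 2.0 * uf.term_sum / m_total
        if d > best_d + 1e-12:
            best_d, best_height = d, height

    # rebuild communities at the best cut
    uf = _EdgeUnionFind(edges)
    for height, e, f, _ in dendrogram:
        if height <= best_height + 1e-12:
            uf.union(e, f)
    groups: dict[int, list[int]] = {}
    for idx in range(m_total):
        groups.setdefault(uf.find(idx), []).append(idx)

    edge_modules: dict[str, frozenset[tuple[str, str]]] = {}
    modules: dict[str, frozenset[str]] = {}
    communities: list[frozenset[tuple[str, str]]] = []
    for rank, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        community = frozenset(edges[i] for i in groups[root])
        communities.append(community)
        name = f"lcm{rank:04d}"
        edge_modules[name] = community
        if len(community) >= 2:
            genes: set[str] = set()
            for a, b in community:
                genes.add(a)
                genes.add(b)
            modules[name] = frozenset(genes)

    d_value = partition_density(communities, m_total)
    module_set = ModuleSet("lcm", modules, edge_modules)
    return LinkCommunityResult(module_set, d_value, best_height, dendrogram)


def module_size_stats(
    ms: ModuleSet, n_network_nodes: int | None = None
) -> dict:
    """Count, median/min/max module size and gene coverage fraction."""
    sizes = sorted(ms.sizes())
    stats: dict = {"count": len(sizes)}
    if sizes:
        stats["median_size"] = float(np.median(sizes))
        stats["min_size"] = sizes[0]
        stats["max_size"] = sizes[-1]
    else:
        stats["median_size"] = stats["min_size"] = stats["max_size"] = None
    if n_network_nodes:
        stats["coverage"] = len(ms.covered_genes()) / n_network_nodes
    else:
        stats["coverage"] = None
    return stats
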