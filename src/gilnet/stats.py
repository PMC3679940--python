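"""Topology metrics and Fisher-exact functional enrichment."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .expression_io import AnnotationSet
from .network_build import CoexpressionNetwork

__all__ = [
    "TopologyReport",
    "EnrichmentResult",
    "degree_stats",
    "average_degree",
    "fit_power_law",
    "clustering_coefficient",
    "fisher_enrichment",
    "bonferroni",
    "enrich_modules",
    "topology_report",
]


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    average_degree: float
    gamma: float | None = None
    mean_clustering: float | None = None


@dataclass
class EnrichmentResult:
    module_id: str
    term_id: str
    vocabulary: str
    k_overlap: int
    term_size: int
    module_size: int
    background_size: int
    p: float
    p_adj: float

    def significant(self, alpha: float = 0.001) -> bool:
        return self.p_adj < alpha


def average_degree(n_nodes: int, n_edges: int) -> float:
    """<k> = 2m / n."""
    if n_nodes <= 0:
        raise ValueError("empty network has no average degree")
    return 2.0 * n_edges / n_nodes


def degree_stats(net: CoexpressionNetwork) -> TopologyReport:
    n, m = net.n_nodes, net.n_edges
    if n == 0:
        raise ValueError("empty network")
    return TopologyReport(n, m, average_degree(n, m))


def fit_power_law(degrees, xmin: int | None = None) -> float:
    """Continuous-approximation MLE of the power-law scaling exponent.

    ``gamma_hat = 1 + n_tail / sum(log(x / (xmin - 0.5)))`` over the tail
    sample ``x >= xmin``.  By default ``xmin`` is the smallest observed
    degree >= 1.
    """
    x = np.asarray(degrees, dtype=float)
    x = x[x >= 1]
    if xmin is None:
        xmin = int(x.min()) if x.size else 1
    tail = x[x >= xmin]
    if tail.size < 2:
        raise ValueError("need at least 2 degrees >= xmin")
    if np.all(tail == tail[0]):
        raise ValueError("all degrees equal; exponent undefined")
    denom = np.log(tail / (xmin - 0.5)).sum()
    return float(1.0 + tail.size / denom)


def _to_nx(net: CoexpressionNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b, _ in net.edges)
    return g


def clustering_coefficient(net: CoexpressionNetwork) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(_to_nx(net)))


def topology_report(net: CoexpressionNetwork) -> TopologyReport:
    report = degree_stats(net)
    report.mean_clustering = clustering_coefficient(net)
    degrees = np.array([d for _, d in _to_nx(net).degree()])
    if np.unique(degrees[degrees >= 1]).size >= 10:
        report.gamma = fit_power_law(degrees)
    return report


def fisher_enrichment(
    module_genes: set[str], term_genes: set[str], background: set[str]
) -> float:
    """One-sided hypergeometric upper tail P(X >= k).

    N = |background|, K = |term ∩ background|, n = |module|,
    k = |module ∩ term|.  The module must be a subset of the background.
    """
    module = set(module_genes)
    if not module <= set(background):
        raise ValueError("module genes must be a subset of the background")
    n_bg = len(background)
    term_in_bg = set(term_genes) & set(background)
    if not module or not term_in_bg:
        warnings.warn("empty module or term within background; p = 1", stacklevel=2)
        return 1.0
    k = len(module & term_in_bg)
    return float(hypergeom.sf(k - 1, n_bg, len(term_in_bg), len(module)))


def bonferroni(p: float, family_size: int) -> float:
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * family_size)


def enrich_modules(
    modules: dict[str, frozenset[str]],
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.001,
    min_module_size: int = 3,
    global_family: bool = False,
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of every module against every term.

    The Bonferroni family is the number of terms tested per module (one
    vocabulary); ``global_family`` switches to the stricter modules x terms
    family.  Modules smaller than ``min_module_size`` genes are skipped.
    Only results significant at ``alpha`` (adjusted) are returned.
    """
    results: list[EnrichmentResult] = []
    tested = {
        mid: genes & background
        for mid, genes in modules.items()
        if len(set(genes) & background) >= min_module_size
    }
    terms = {
        tid: set(annotations.genes_for(tid)) & background
        for tid in annotations.terms
    }
    terms = {tid: g for tid, g in terms.items() if g}
    if not terms:
        return results
    family = len(terms) * (len(tested) if global_family else 1)
    for mid, module in tested.items():
        for tid, term in terms.items():
            k = len(module & term)
            if k == 0:
                continue
            p = float(
                hypergeom.sf(k - 1, len(background), len(term), len(module))
            )
            p_adj = bonferroni(p, family)
            if p_adj < alpha:
                results.append(
                    EnrichmentResult(
                        mid, tid, annotations.vocabulary, k, len(term),
                        len(module), len(background), p, p_adj,
                    )
                )
    return results
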