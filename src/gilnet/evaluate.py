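"""Compendium-level experiments.

Builds the full set of per-cluster networks for one K, accumulates
node/edge capture across K values, runs randomization controls, and
annotates clusters with keywords mined from free-text sample descriptions.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .expression_io import (
    AnnotationSet,
    ExpressionMatrix,
    ProbeGeneMap,
    SampleMetadata,
)
from .modules_detect import (
    LinkCommunityResult,
    ModuleSet,
    link_communities,
    mcl,
)
from .network_build import (
    CoexpressionNetwork,
    RMTResult,
    UnbuildableClusterError,
    collapse_probes_to_genes,
    extract_network,
    pearson_matrix,
    rmt_threshold,
)
from .partition import SamplePartition, kmeans_partition
from .preprocess import (
    drop_ambiguous_probes,
    drop_control_probes,
    drop_outlier_samples,
    quantile_normalize,
)
from .stats import EnrichmentResult, TopologyReport, enrich_modules, topology_report

__all__ = [
    "BuildConfig",
    "GILRecord",
    "GILCompendium",
    "CaptureCurve",
    "build_compendium",
    "capture_curve",
    "compendium_summary",
    "coverage_percent",
    "mean_arrays_per_cluster",
    "extrapolate_interactome",
    "edge_overlap",
    "overlap_percent",
    "assign_keywords",
    "tokenize",
    "keyword_enrichment_ratio",
    "order_gils",
    "keyword_adjacency_pvalue",
    "unique_enriched_terms",
]


@dataclass
class BuildConfig:
    control_prefixes: tuple[str, ...] = ("AFFX",)
    remove_outliers: bool = True
    quantile_norm: bool = True
    min_cluster_samples: int = 10
    t_start: float = 0.99
    t_stop: float = 0.50
    t_step: float = 0.001
    chi_crit: float = 99.607
    min_eigenvalues: int = 100
    mcl_inflation: float = 2.0
    mcl_pruning: float = 1e-5
    run_lcm: bool = True


@dataclass
class GILRecord:
    cluster: int
    status: str  # "built" | "n.a."
    reason: str | None = None
    sample_ids: list[str] = field(default_factory=list)
    network: CoexpressionNetwork | None = None
    rmt: RMTResult | None = None
    mcl_modules: ModuleSet | None = None
    lcm: LinkCommunityResult | None = None
    topology: TopologyReport | None = None

    @property
    def built(self) -> bool:
        return self.status == "built"


@dataclass
class GILCompendium:
    K: int
    seed: int
    partition: SamplePartition
    gils: dict[int, GILRecord]

    @property
    def built_gils(self) -> list[GILRecord]:
        return [g for g in self.gils.values() if g.built]

    @property
    def success_rate(self) -> float:
        return len(self.built_gils) / self.K

    def unique_nodes(self) -> set[str]:
        nodes: set[str] = set()
        for g in self.built_gils:
            nodes |= set(g.network.nodes)
        return nodes

    def unique_edges(self) -> set[tuple[str, str]]:
        edges: set[tuple[str, str]] = set()
        for g in self.built_gils:
            edges |= g.network.edge_pairs()
        return edges


@dataclass
class CaptureCurve:
    points: list[tuple[int, int, int, float]]
    # (K, unique nodes, unique edges, success rate), ordered by K


def _build_cluster(
    X: ExpressionMatrix,
    cluster: int,
    sample_ids: list[str],
    config: BuildConfig,
    pmap: ProbeGeneMap | None,
) -> GILRecord:
    record = GILRecord(cluster, "n.a.", sample_ids=sample_ids)
    try:
        sub = X.subset_samples(sample_ids)
        if sub.n_samples < config.min_cluster_samples:
            record.reason = "too few samples"
            return record
        sub = drop_control_probes(sub, list(config.control_prefixes))
        if sub.n_genes == 0:
            record.reason = "no probes remain"
            return record
        if config.quantile_norm:
            sub = quantile_normalize(sub)
        if config.remove_outliers and sub.n_samples >= 4:
            sub, _ = drop_outlier_samples(sub)
        if pmap is not None:
            sub = drop_ambiguous_probes(sub, pmap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = pearson_matrix(sub, min_samples=config.min_cluster_samples)
        rmt = rmt_threshold(
            sim,
            t_start=config.t_start,
            t_stop=config.t_stop,
            step=config.t_step,
            chi_crit=config.chi_crit,
            min_eigenvalues=config.min_eigenvalues,
        )
        record.rmt = rmt
        if not rmt.success:
            record.reason = rmt.failure_reason
            return record
        net = extract_network(sim, rmt.threshold)
        if pmap is not None:
            net = collapse_probes_to_genes(net, pmap)
        if net.n_edges == 0:
            record.reason = "empty network"
            return record
        net.provenance.update({"cluster": cluster, "n_samples": sub.n_samples})
        record.network = net
        record.mcl_modules = mcl(
            net, inflation=config.mcl_inflation, pruning=config.mcl_pruning
        )
        if config.run_lcm:
            record.lcm = link_communities(net)
        record.topology = topology_report(net)
        record.status = "built"
        record.reason = None
    except UnbuildableClusterError as exc:
        record.reason = str(exc)
    return record


def build_compendium(
    X: ExpressionMatrix,
    K: int,
    config: BuildConfig | None = None,
    seed: int = 0,
    pmap: ProbeGeneMap | None = None,
    partition: SamplePartition | None = None,
) -> GILCompendium:
    """Partition samples and build one network per cluster.

    Clusters that fail any construction step are recorded as ``n.a.`` with
    a reason; a failing cluster never aborts the compendium.  ``partition``
    overrides the internal k-means (e.g. for randomized controls).
    """
    config = config or BuildConfig()
    if partition is None:
        partition = kmeans_partition(X, K, seed=seed)
    gils: dict[int, GILRecord] = {}
    for cluster in range(K):
        members = partition.members(cluster)
        gils[cluster] = _build_cluster(X, cluster, members, config, pmap)
    return GILCompendium(K, seed, partition, gils)


def capture_curve(compendia: Iterable[GILCompendium]) -> CaptureCurve:
    points = []
    for comp in sorted(compendia, key=lambda c: c.K):
        points.append(
            (
                comp.K,
                len(comp.unique_nodes()),
                len(comp.unique_edges()),
                comp.success_rate,
            )
        )
    if not points:
        raise ValueError("need at least one compendium")
    return CaptureCurve(points)


def coverage_percent(captured: int, measurable: int) -> float:
    """Percent of measurable genes captured, one decimal."""
    if measurable <= 0:
        raise ValueError("measurable gene count must be positive")
    return round(100.0 * captured / measurable, 1)


def mean_arrays_per_cluster(n_samples: int, K: int) -> float:
    return round(n_samples / K, 1)


def compendium_summary(
    compendium: GILCompendium,
    n_measurable: int,
    metadata: SampleMetadata | None = None,
) -> dict:
    """Coverage, capture and per-GIL array/series summaries."""
    if n_measurable <= 0:
        raise ValueError("n_measurable must be positive")
    nodes = compendium.unique_nodes()
    edges = compendium.unique_edges()
    n_samples = len(compendium.partition.assignment)
    summary = {
        "K": compendium.K,
        "n_gils_built": len(compendium.built_gils),
        "success_rate": compendium.success_rate,
        "unique_nodes": len(nodes),
        "unique_edges": len(edges),
        "coverage_percent": coverage_percent(len(nodes), n_measurable),
        "mean_arrays_per_cluster": mean_arrays_per_cluster(n_samples, compendium.K),
    }
    arrays = [len(g.sample_ids) for g in compendium.built_gils]
    if arrays:
        summary["arrays_per_gil_mean"] = round(float(np.mean(arrays)), 1)
        summary["arrays_per_gil_sd"] = round(float(np.std(arrays)), 1)
    if metadata is not None:
        series_counts = [
            len({metadata.series_of(s) for s in g.sample_ids})
            for g in compendium.built_gils
        ]
        if series_counts:
            summary["series_per_gil_mean"] = round(float(np.mean(series_counts)), 1)
            summary["series_per_gil_sd"] = round(float(np.std(series_counts)), 1)
    return summary


def extrapolate_interactome(
    unique_edges: int, captured_genes: int, measurable_genes: int
) -> int:
    """Scale the edge union linearly up to the full measurable gene space."""
    if captured_genes <= 0:
        raise ValueError("captured gene count must be positive")
    return math.floor(unique_edges * measurable_genes / captured_genes)


def overlap_percent(count: int, total: int) -> float | None:
    if total == 0:
        return None
    return round(100.0 * count / total, 1)


def edge_overlap(
    a: set[tuple[str, str]], b: set[tuple[str, str]]
) -> tuple[int, float | None]:
    """Intersection size of two canonical edge sets and percent of ``b``."""
    count = len(a & b)
    return count, overlap_percent(count, len(b))


_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str, min_length: int = 3) -> list[str]:
    """ASCII lowercase, split on non-alphanumerics, keep length >= 3."""
    return [t for t in _TOKEN_RE.split(text.lower()) if len(t) >= min_length]


def assign_keywords(
    descriptions: Iterable[str],
    stoplist: set[str] = frozenset(),
    top_n: int = 10,
) -> list[str]:
    """Top ``top_n`` non-stoplist words by frequency, ties alphabetical."""
    counts: dict[str, int] = {}
    for description in descriptions:
        for token in tokenize(description):
            if token not in stoplist:
                counts[token] = counts.get(token, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [w for w, _ in ranked[:top_n]]


def compendium_keywords(
    compendium: GILCompendium,
    metadata: SampleMetadata,
    stoplist: set[str] = frozenset(),
    top_n: int = 10,
) -> dict[int, list[str]]:
    """Per-GIL keyword lists from the member samples' descriptions."""
    out: dict[int, list[str]] = {}
    for cluster, record in compendium.gils.items():
        descriptions = [metadata.description_of(s) for s in record.sample_ids]
        out[cluster] = assign_keywords(descriptions, stoplist, top_n)
    return out


def unique_enriched_terms(
    compendium: GILCompendium,
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.001,
    module_source: str = "mcl",
) -> set[str]:
    """Union of term ids significantly enriched in any built GIL's modules."""
    terms: set[str] = set()
    for record in compendium.built_gils:
        modules = _modules_of(record, module_source)
        if modules is None:
            continue
        for res in enrich_modules(modules, annotations, background, alpha=alpha):
            terms.add(res.term_id)
    return terms


def _modules_of(record: GILRecord, source: str):
    if source == "mcl":
        return record.mcl_modules.modules if record.mcl_modules else None
    if source == "lcm":
        return record.lcm.module_set.modules if record.lcm else None
    raise ValueError(f"unknown module source {source!r}")


def keyword_enrichment_ratio(
    compendium: GILCompendium,
    keywords_per_gil: Mapping[int, list[str]],
    keyword: str,
    pattern: str,
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.001,
    module_source: str = "lcm",
    normalize: bool = True,
) -> float:
    """Ratio of pattern-matching enriched-term descriptions, keyword vs not.

    GILs are split by presence of ``keyword`` in their keyword list; in
    each group, enrichment results whose term description contains
    ``pattern`` (case-insensitive substring) are counted.  With
    ``normalize`` the counts are divided by group size first.  A zero
    non-keyword count with a positive keyword count yields ``inf``.
    """
    kw_group = [c for c in compendium.gils if keyword in keywords_per_gil.get(c, [])]
    non_group = [c for c in compendium.gils if c not in set(kw_group)]
    if not kw_group or not non_group:
        raise ValueError("both keyword and non-keyword groups must be non-empty")
    pattern_lower = pattern.lower()

    def group_count(clusters: list[str]) -> int:
        count = 0
        for c in clusters:
            record = compendium.gils[c]
            if not record.built:
                continue
            modules = _modules_of(record, module_source)
            if modules is None:
                continue
            for res in enrich_modules(modules, annotations, background, alpha=alpha):
                if pattern_lower in annotations.description_for(res.term_id).lower():
                    count += 1
        return count

    count_kw = group_count(kw_group)
    count_non = group_count(non_group)
    if normalize:
        rate_kw = count_kw / len(kw_group)
        rate_non = count_non / len(non_group)
    else:
        rate_kw, rate_non = float(count_kw), float(count_non)
    if rate_non == 0:
        return math.inf if rate_kw > 0 else math.nan
    return rate_kw / rate_non


def order_gils(
    compendium: GILCompendium,
) -> tuple[list[int], np.ndarray, list[int]]:
    """Order built GILs by shared link-community gene content.

    Similarity(a, b) = number of genes covered by both GILs' link-community
    modules; GILs are average-linkage clustered on ``max_sim - sim`` and the
    dendrogram leaf order is returned along with the similarity matrix and
    the list of GIL ids the matrix indexes.
    """
    ids = [c for c, g in compendium.gils.items() if g.built and g.lcm is not None]
    if len(ids) < 2:
        raise ValueError("need at least 2 built GILs with link communities")
    covered = [compendium.gils[c].lcm.module_set.covered_genes() for c in ids]
    n = len(ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sim[i, j] = sim[j, i] = len(covered[i] & covered[j])
    dist = sim.max() - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = leaves_list(z).tolist()
    return [ids[i] for i in order], sim, ids


def keyword_adjacency_pvalue(
    leaf_order: list[int],
    keywords_per_gil: Mapping[int, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for non-random keyword clustering along an order.

    Statistic: number of adjacent leaf pairs sharing at least one keyword.
    Keyword lists are shuffled across GILs ``n_permutations`` times.
    """
    keyword_sets = [frozenset(keywords_per_gil.get(c, [])) for c in leaf_order]

    def statistic(sets: list[frozenset[str]]) -> int:
        return sum(
            1 for a, b in zip(sets, sets[1:]) if a & b
        )

    observed = statistic(keyword_sets)
    rng = np.random.default_rng(seed)
    at_least = 1  # permutation p-value includes the observed arrangement
    for _ in range(n_permutations):
        perm = rng.permutation(len(keyword_sets))
        if statistic([keyword_sets[i] for i in perm]) >= observed:
            at_least += 1
    return at_least / (n_permutations + 1)
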