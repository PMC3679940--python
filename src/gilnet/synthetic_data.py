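"""Generators for every input the pipeline consumes.

A latent-factor model plants condition-specific co-expressed modules with a
known within-module correlation of ``b**2 / (b**2 + sigma**2)``, so
threshold-detection and recovery tests run against an exact signal level.
Optional per-condition marker genes carry a constant mean shift that makes
conditions separable in sample space (the factor model alone centers every
condition on the same point, which K-means cannot distinguish).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix, SampleMetadata

__all__ = [
    "CompendiumTruth",
    "simulate_compendium",
    "simulate_power_law_degrees",
    "simulate_planted_partition_graph",
    "annotation_terms_from_truth",
    "DEFAULT_KEYWORDS",
]

DEFAULT_KEYWORDS = (
    "root", "leaf", "seed", "seedling", "flower", "stress",
    "light", "auxin", "iron", "mutant",
)


@dataclass
class CompendiumTruth:
    """Ground truth of a simulated compendium."""

    condition_of_sample: dict[str, int]
    planted_modules: dict[int, list[frozenset[str]]]
    loading: float
    noise_sd: float
    marker_genes: dict[int, frozenset[str]] = field(default_factory=dict)
    keyword_of_condition: dict[int, str] = field(default_factory=dict)

    @property
    def expected_within_module_r(self) -> float:
        b2 = self.loading ** 2
        return b2 / (b2 + self.noise_sd ** 2)

    def module_pairs(self, condition: int) -> set[tuple[str, str]]:
        """Canonical within-module gene pairs planted for one condition."""
        pairs: set[tuple[str, str]] = set()
        for module in self.planted_modules[condition]:
            genes = sorted(module)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    pairs.add((a, b))
        return pairs

    def all_module_pairs(self) -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        for condition in self.planted_modules:
            pairs |= self.module_pairs(condition)
        return pairs


def simulate_compendium(
    n_genes: int,
    n_samples: int,
    n_conditions: int,
    modules_per_condition: int,
    module_size: int,
    loading: float,
    noise_sd: float,
    seed: int,
    *,
    marker_genes_per_condition: int = 0,
    marker_shift: float = 0.0,
    baseline_sd: float = 1.0,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
) -> tuple[ExpressionMatrix, SampleMetadata, CompendiumTruth]:
    """Simulate a multi-condition expression compendium.

    Samples are split evenly across conditions.  For a planted module M of
    condition c, a gene g in M measured in a sample s of condition c follows
    ``x = mu_g + loading * z_{M,s} + eps`` with ``z_{M,s}`` a standard-normal
    factor drawn per module and sample and ``eps ~ N(0, noise_sd**2)``; all
    other entries are ``mu_g + eps``.  Marker genes of condition c gain a
    constant ``marker_shift`` in samples of c.  Deterministic given ``seed``.
    """
    if modules_per_condition * module_size > n_genes:
        raise ValueError("modules_per_condition * module_size exceeds n_genes")
    if n_samples < 2 * n_conditions:
        raise ValueError("need at least 2 samples per condition")
    if marker_genes_per_condition * n_conditions > n_genes:
        raise ValueError("too many marker genes requested")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]

    condition_of_sample = {
        s: j % n_conditions for j, s in enumerate(sample_ids)
    }

    # markers first (disjoint across conditions), modules from the rest
    gene_order = rng.permutation(n_genes)
    marker_genes: dict[int, frozenset[str]] = {}
    cursor = 0
    for c in range(n_conditions):
        block = gene_order[cursor:cursor + marker_genes_per_condition]
        marker_genes[c] = frozenset(gene_ids[i] for i in block)
        cursor += marker_genes_per_condition
    module_pool = gene_order[cursor:]

    planted_modules: dict[int, list[frozenset[str]]] = {}
    for c in range(n_conditions):
        picked = rng.choice(
            module_pool, size=modules_per_condition * module_size, replace=False
        )
        planted_modules[c] = [
            frozenset(
                gene_ids[i]
                for i in picked[m * module_size:(m + 1) * module_size]
            )
            for m in range(modules_per_condition)
        ]

    mu = rng.normal(0.0, baseline_sd, size=n_genes)
    values = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    cond_array = np.array([condition_of_sample[s] for s in sample_ids])
    for c in range(n_conditions):
        cols = np.flatnonzero(cond_array == c)
        for module in planted_modules[c]:
            z = rng.normal(0.0, 1.0, size=cols.size)
            rows = np.array([gene_index[g] for g in sorted(module)])
            values[np.ix_(rows, cols)] += loading * z[None, :]
        if marker_genes_per_condition and marker_shift:
            rows = np.array([gene_index[g] for g in sorted(marker_genes[c])])
            values[np.ix_(rows, cols)] += marker_shift

    keyword_of_condition = {
        c: keywords[c % len(keywords)] for c in range(n_conditions)
    }
    meta = SampleMetadata()
    for j, s in enumerate(sample_ids):
        c = condition_of_sample[s]
        kw = keyword_of_condition[c]
        meta.add(
            s,
            f"series{c:03d}",
            f"expression profiling of {kw} tissue replicate {j}",
        )

    truth = CompendiumTruth(
        condition_of_sample=condition_of_sample,
        planted_modules=planted_modules,
        loading=loading,
        noise_sd=noise_sd,
        marker_genes=marker_genes,
        keyword_of_condition=keyword_of_condition,
    )
    return ExpressionMatrix(gene_ids, sample_ids, values), meta, truth


def simulate_power_law_degrees(
    n: int,
    gamma: float,
    xmin: int = 1,
    seed: int = 0,
    *,
    k_max: int = 10 ** 6,
) -> np.ndarray:
    """Draw ``n`` i.i.d. values from ``P(k) \\propto k**-gamma`` for k >= xmin.

    Inverse-CDF sampling on the support truncated at ``k_max``; the mass
    beyond the truncation point is negligible for gamma > 1 at the default.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1 (distribution not normalizable)")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    rng = np.random.default_rng(seed)
    support = np.arange(xmin, k_max + 1, dtype=float)
    weights = support ** (-gamma)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    return (idx + xmin).astype(int)


def simulate_planted_partition_graph(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Undirected planted-partition graph.

    Nodes ``0 .. sum(block_sizes)-1`` are assigned to blocks in order; a
    within-block pair is an edge with probability ``p_in``, a between-block
    pair with ``p_out``.  Returns the edge list and the block label of each
    node.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, p_in, p_out)
    keep = rng.random(iu.size) < p
    edges = [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]
    return edges, labels


def annotation_terms_from_truth(
    truth: CompendiumTruth,
    gene_ids: list[str],
    *,
    n_random_terms: int = 0,
    random_term_size: int = 20,
    seed: int = 0,
    vocabulary: str = "SYN",
):
    """Build an annotation set whose terms mirror the planted modules.

    Each planted module becomes one term whose description embeds the
    condition keyword, so keyword/enrichment analyses have a known answer;
    optional random distractor terms are appended.
    """
    from .expression_io import AnnotationSet

    annot = AnnotationSet(vocabulary)
    for c in sorted(truth.planted_modules):
        kw = truth.keyword_of_condition.get(c, f"cond{c}")
        for m, module in enumerate(truth.planted_modules[c]):
            annot.add(f"{vocabulary}:C{c}M{m}", f"{kw} response module {m}", module)
    rng = np.random.default_rng(seed)
    for t in range(n_random_terms):
        genes = rng.choice(gene_ids, size=min(random_term_size, len(gene_ids)),
                           replace=False)
        annot.add(f"{vocabulary}:R{t}", f"unrelated process {t}", genes)
    return annot
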