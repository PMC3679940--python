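"""Sample pre-clustering and randomized controls.

Samples are points in gene-expression space; Lloyd's algorithm with
multiple random restarts assigns each to one of K clusters.  The
randomization control permutes a fraction of the labels while keeping the
multiset of cluster sizes exactly intact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .expression_io import ExpressionMatrix

__all__ = ["SamplePartition", "kmeans_partition", "randomize_partition"]


@dataclass
class SamplePartition:
    K: int
    assignment: dict[str, int]  # sample_id -> cluster index in [0, K)
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        for s, c in self.assignment.items():
            if not 0 <= c < self.K:
                raise ValueError(f"sample {s!r} assigned to invalid cluster {c}")

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]

    def sizes(self) -> list[int]:
        counts = [0] * self.K
        for c in self.assignment.values():
            counts[c] += 1
        return counts

    def labels(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[s] for s in sample_ids])


def _lloyd(
    data: np.ndarray, K: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, float, bool]:
    m = data.shape[0]
    centers = data[rng.choice(m, size=K, replace=False)].copy()
    prev_inertia = math.inf
    converged = False
    labels = np.zeros(m, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(data, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        # re-seed empty clusters from the farthest point
        reseeded = False
        for k in range(K):
            if not (labels == k).any():
                farthest = int(d2.min(axis=1).argmax())
                centers[k] = data[farthest]
                reseeded = True
        if reseeded:
            d2 = cdist(data, centers, "sqeuclidean")
            labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(m), labels].sum())
        # Lloyd's objective never increases between iterations
        assert inertia <= prev_inertia + 1e-6 * (1 + abs(prev_inertia))
        if prev_inertia - inertia <= 1e-10 * (1 + inertia):
            converged = True
            prev_inertia = inertia
            break
        prev_inertia = inertia
        for k in range(K):
            centers[k] = data[labels == k].mean(axis=0)
    return labels, prev_inertia, converged


def kmeans_partition(
    X: ExpressionMatrix,
    K: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    standardize_genes: bool = False,
) -> SamplePartition:
    """Cluster samples into K groups by Euclidean distance over all genes.

    Best of ``n_init`` random initializations by inertia; deterministic
    given ``seed``.  With ``standardize_genes`` each gene is centered and
    scaled to unit variance first (off by default: clustering acts on raw
    normalized expression values).
    """
    if K > X.n_samples:
        raise ValueError(f"K={K} exceeds number of samples {X.n_samples}")
    if K < 1:
        raise ValueError("K must be >= 1")
    if np.isnan(X.values).any():
        raise ValueError("k-means requires complete values")
    data = X.values.T.copy()
    if standardize_genes:
        sd = data.std(axis=0)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, math.inf
    any_converged = False
    for _ in range(n_init):
        labels, inertia, converged = _lloyd(data, K, rng, max_iter)
        any_converged = any_converged or converged
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    if not any_converged:
        warnings.warn(
            f"k-means did not converge within {max_iter} iterations", stacklevel=2
        )
    assignment = {s: int(c) for s, c in zip(X.sample_ids, best_labels)}
    return SamplePartition(K, assignment, seed, best_inertia)


def randomize_partition(
    P: SamplePartition, fraction: float, seed: int = 0
) -> SamplePartition:
    """Permute the cluster labels of ``floor(fraction * m)`` random samples.

    The selected samples exchange labels among themselves via a uniform
    random permutation, so cluster count and sizes are preserved exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = list(P.assignment)
    m = len(samples)
    n_pick = int(math.floor(fraction * m))
    picked = rng.choice(m, size=n_pick, replace=False)
    labels = [P.assignment[samples[i]] for i in picked]
    permuted = rng.permutation(n_pick)
    assignment = dict(P.assignment)
    for slot, i in enumerate(picked):
        assignment[samples[i]] = labels[permuted[slot]]
    return SamplePartition(P.K, assignment, seed, math.nan)
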