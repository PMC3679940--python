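"""Similarity matrices, spectral threshold detection and network extraction.

The correlation threshold for each sample cluster is found by scanning
candidate cutoffs from high to low and, at each one, testing whether the
nearest-neighbor spacing distribution (NNSD) of the thresholded matrix's
unfolded eigenvalues is still Poisson-like.  Modular (signal) matrices
produce Poisson spacings; once noise floods in, spacings shift toward the
Gaussian orthogonal ensemble and the chi-square against the Poisson law
explodes.  The chosen threshold is the last scanned value before that
transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import eigvalsh

from .expression_io import ExpressionMatrix, ProbeGeneMap, canonical_pair

__all__ = [
    "SimilarityMatrix",
    "RMTScanPoint",
    "RMTResult",
    "CoexpressionNetwork",
    "UnbuildableClusterError",
    "pearson_matrix",
    "unfold_eigenvalues",
    "nnsd_chi_square",
    "rmt_threshold",
    "extract_network",
    "collapse_probes_to_genes",
    "CHI_SQUARE_CRITICAL",
]

# chi-square upper 0.1% point at 60 histogram bins
CHI_SQUARE_CRITICAL = 99.607


class UnbuildableClusterError(ValueError):
    """Raised when a cluster cannot support network construction."""


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, |r| <= 1
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")


@dataclass
class RMTScanPoint:
    threshold: float
    retained_dim: int
    n_unique_eigenvalues: int
    chi_square: float


@dataclass
class RMTResult:
    threshold: float | None
    scan: list[RMTScanPoint] = field(default_factory=list)
    failure_reason: str | None = None

    @property
    def success(self) -> bool:
        return self.threshold is not None


@dataclass
class CoexpressionNetwork:
    """Thresholded edge list with signed correlations; pairs canonical."""

    edges: list[tuple[str, str, float]]
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = []
        seen: set[tuple[str, str]] = set()
        for a, b, r in self.edges:
            pair = canonical_pair(a, b)
            if pair in seen:
                raise ValueError(f"duplicate edge {pair}")
            seen.add(pair)
            canon.append((*pair, float(r)))
        self.edges = sorted(canon)

    @property
    def nodes(self) -> list[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}


def pearson_matrix(
    X: ExpressionMatrix,
    min_samples: int = 10,
    max_missing_fraction: float = 0.2,
) -> SimilarityMatrix:
    """Pairwise Pearson correlation of rows over pairwise-complete samples.

    Rows with zero variance, or with more than ``max_missing_fraction``
    missing values, are dropped with a warning before computation.
    """
    if X.n_samples < min_samples:
        raise UnbuildableClusterError(
            f"cluster has {X.n_samples} samples; need >= {min_samples}"
        )
    values = X.values
    missing = np.isnan(values)
    frac_missing = missing.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_var = np.nanvar(values, axis=1)
    keep = (frac_missing <= max_missing_fraction) & (row_var > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} rows (zero variance or too many missing)",
            stacklevel=2,
        )
    ids = [g for g, k in zip(X.gene_ids, keep) if k]
    sub = values[keep]
    if not ids:
        raise UnbuildableClusterError("no usable rows for correlation")
    if np.isnan(sub).any():
        import pandas as pd

        corr = pd.DataFrame(sub.T).corr(min_periods=3).to_numpy()
    else:
        corr = np.corrcoef(sub)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(ids, corr, X.n_samples)


def _dedup_sorted(values: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Collapse sorted values closer than ``tol`` to their first member."""
    if values.size == 0:
        return values
    out = [values[0]]
    for v in values[1:]:
        if v - out[-1] > tol:
            out.append(v)
    return np.asarray(out)


def unfold_eigenvalues(
    eigenvalues: np.ndarray,
    fit_knots: int = 10,
    min_eigenvalues: int = 100,
    dedup_tol: float = 1e-8,
) -> np.ndarray:
    """Map a spectrum onto a scale with unit mean nearest-neighbor spacing.

    A monotone cubic (PCHIP) approximation of the empirical cumulative
    spectral count is fitted through every ``fit_knots``-th distinct
    eigenvalue, the spectrum is passed through it, and the result is
    rescaled so the mean spacing is exactly 1.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    distinct = _dedup_sorted(ev, dedup_tol)
    n = distinct.size
    if n < min_eigenvalues:
        raise UnbuildableClusterError(
            f"{n} distinct eigenvalues; need >= {min_eigenvalues}"
        )
    idx = np.arange(0, n, fit_knots)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    # PCHIP through the knots keeps the cumulative count monotone
    spline = PchipInterpolator(distinct[idx], idx.astype(float))
    unfolded = np.asarray(spline(distinct), dtype=float)
    unfolded = np.maximum.accumulate(unfolded)
    span = unfolded[-1] - unfolded[0]
    if span <= 0:
        raise UnbuildableClusterError("degenerate unfolded spectrum")
    return (unfolded - unfolded[0]) * (n - 1) / span


def nnsd_chi_square(
    unfolded: np.ndarray, n_bins: int = 60, s_max: float = 3.0
) -> float:
    """Chi-square of the NNSD against the Poisson (exponential) law.

    Spacings of the unfolded spectrum are histogrammed on ``n_bins`` equal
    bins over ``[0, s_max]``; the expected count in bin ``[lo, hi)`` under
    the Poisson law is ``N * (exp(-lo) - exp(-hi))`` with N the total
    number of spacings.
    """
    unfolded = np.asarray(unfolded, dtype=float)
    if unfolded.size < 2:
        raise ValueError("need at least 2 unfolded values")
    spacings = np.diff(np.sort(unfolded))
    n = spacings.size
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(spacings, bins=edges)
    expected = n * (np.exp(-edges[:-1]) - np.exp(-edges[1:]))
    mask = expected > 0
    return float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())


def rmt_threshold(
    S: SimilarityMatrix,
    t_start: float = 0.99,
    t_stop: float = 0.50,
    step: float = 0.001,
    chi_crit: float = CHI_SQUARE_CRITICAL,
    chi_stop: float = 200.0,
    n_bins: int = 60,
    s_max: float = 3.0,
    min_eigenvalues: int = 100,
    fit_knots: int = 10,
) -> RMTResult:
    """Scan thresholds downward and stop at the Poisson-to-GOE transition.

    At each candidate ``t`` the rows/columns with at least one off-diagonal
    ``|r| >= t`` are kept, sub-threshold entries are zeroed, the diagonal is
    set to 1, and the NNSD chi-square of the unfolded eigenvalues is
    computed.  The scan terminates once the chi-square clearly explodes
    (``> chi_stop``); the chosen threshold is the lowest scanned ``t`` whose
    chi-square stayed at or below the selection criterion ``chi_crit``.
    The two-level rule tolerates isolated noise spikes in the chi-square
    trace (the spacing histogram is noisy near the minimum eigenvalue
    count) without mistaking them for the transition.  The scan fails if no
    usable point ever satisfies ``chi_crit`` ("never Poisson-like"), or if
    no scanned point yields enough distinct eigenvalues ("matrix too
    small").
    """
    A = np.abs(S.values.copy())
    np.fill_diagonal(A, 0.0)
    row_max = A.max(axis=1) if A.size else np.empty(0)
    thresholds = np.arange(t_start, t_stop - step / 2, -step)

    scan: list[RMTScanPoint] = []
    last_good_t: float | None = None
    prev_signature: tuple[int, int] | None = None
    prev_chi: float | None = None
    prev_n_unique = 0
    for t in thresholds:
        t = float(round(t, 10))
        keep = row_max >= t
        dim = int(keep.sum())
        if dim < 2:
            continue
        n_entries = int((A[np.ix_(keep, keep)] >= t).sum())
        signature = (dim, n_entries)
        if signature == prev_signature and prev_chi is not None:
            chi = prev_chi
            n_unique = prev_n_unique
        else:
            sub = S.values[np.ix_(keep, keep)].copy()
            sub[np.abs(sub) < t] = 0.0
            np.fill_diagonal(sub, 1.0)
            ev = eigvalsh(sub)
            distinct = _dedup_sorted(np.sort(ev))
            n_unique = distinct.size
            if n_unique < min_eigenvalues:
                prev_signature, prev_chi = signature, None
                continue
            unfolded = unfold_eigenvalues(
                distinct, fit_knots=fit_knots, min_eigenvalues=min_eigenvalues
            )
            chi = nnsd_chi_square(unfolded, n_bins=n_bins, s_max=s_max)
            prev_signature, prev_chi, prev_n_unique = signature, chi, n_unique
        scan.append(RMTScanPoint(t, dim, n_unique, chi))
        if chi > chi_stop:
            break
        if chi <= chi_crit:
            last_good_t = t
    if last_good_t is None:
        reason = "never Poisson-like" if scan else "matrix too small"
        return RMTResult(None, scan, reason)
    return RMTResult(last_good_t, scan)


def extract_network(S: SimilarityMatrix, t: float) -> CoexpressionNetwork:
    """Edge for every pair with ``|r| >= t``; isolated nodes excluded."""
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    absval = np.abs(S.values)
    iu, ju = np.triu_indices(len(S.ids), k=1)
    keep = absval[iu, ju] >= t
    edges = [
        (S.ids[i], S.ids[j], float(S.values[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]
    return CoexpressionNetwork(edges, threshold=t)


def collapse_probes_to_genes(
    net: CoexpressionNetwork, pmap: ProbeGeneMap
) -> CoexpressionNetwork:
    """Rename probe nodes to genes, resolving collisions by maximum |r|.

    Every node must map to exactly one gene.  When several probe pairs land
    on the same gene pair the edge with the largest ``|r|`` wins; pairs of
    probes for a single gene are dropped.
    """
    best: dict[tuple[str, str], float] = {}
    for a, b, r in net.edges:
        ga, gb = pmap.unique_gene(a), pmap.unique_gene(b)
        if ga == gb:
            continue
        pair = canonical_pair(ga, gb)
        if pair not in best or abs(r) > abs(best[pair]):
            best[pair] = r
    edges = [(a, b, r) for (a, b), r in best.items()]
    return CoexpressionNetwork(
        edges, threshold=net.threshold, provenance=dict(net.provenance)
    )
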