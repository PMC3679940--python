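"""Per-cluster expression preprocessing.

Control-probe removal, quantile normalization, outlier-sample removal and
ambiguous-probe removal.  Each removal is recorded with a reason code so a
run can account for every row and column it dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .expression_io import ExpressionMatrix, ProbeGeneMap

__all__ = [
    "OutlierReport",
    "RemovalLog",
    "drop_control_probes",
    "quantile_normalize",
    "detect_outlier_samples",
    "drop_outlier_samples",
    "drop_ambiguous_probes",
]


@dataclass
class RemovalLog:
    """Identifiers removed by a preprocessing step, with a reason code."""

    removed: dict[str, str] = field(default_factory=dict)  # id -> reason

    def record(self, identifier: str, reason: str) -> None:
        self.removed[identifier] = reason


@dataclass
class OutlierReport:
    """Three outlier scores per sample plus flags and the removal verdict.

    A sample is removed iff it fails at least two of the three tests;
    each test flags scores above the Tukey fence Q3 + 1.5*IQR.
    """

    sample_ids: list[str]
    distance_score: np.ndarray       # mean (1 - Pearson r) to other samples
    ks_score: np.ndarray             # KS statistic vs pooled distribution
    deviation_score: np.ndarray      # median |x - row-median reference|
    flags: np.ndarray                # (n_samples, 3) bool
    removed: np.ndarray              # bool

    def removed_samples(self) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.removed) if r]

    def to_rows(self) -> list[tuple]:
        rows = []
        for i, s in enumerate(self.sample_ids):
            rows.append(
                (
                    s,
                    float(self.distance_score[i]),
                    float(self.ks_score[i]),
                    float(self.deviation_score[i]),
                    int(self.flags[i, 0]),
                    int(self.flags[i, 1]),
                    int(self.flags[i, 2]),
                    int(self.removed[i]),
                )
            )
        return rows


def drop_control_probes(
    X: ExpressionMatrix,
    control_prefixes: list[str] = ["AFFX"],
    log: RemovalLog | None = None,
) -> ExpressionMatrix:
    """Remove rows whose identifier starts with any control prefix."""
    prefixes = tuple(control_prefixes)
    keep = []
    for g in X.gene_ids:
        if prefixes and g.startswith(prefixes):
            if log is not None:
                log.record(g, "control_probe")
        else:
            keep.append(g)
    return X.subset_genes(keep)


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common row-rank-mean distribution.

    Ties within a column receive the mean of the reference values at the
    tied positions (average-rank convention).
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(X.values).any():
        raise ValueError("quantile normalization requires complete values")
    values = X.values
    n = X.n_genes
    sorted_cols = np.sort(values, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(X.n_samples):
        ranks = sps.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), out)


def _tukey_flags(scores: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(scores, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return scores > fence


def detect_outlier_samples(X: ExpressionMatrix) -> OutlierReport:
    """Score each sample with three outlier tests and combine them.

    Tests: (1) mean inter-sample distance ``1 - r``; (2) two-sample KS
    statistic of the sample's values against the pooled values of all
    samples; (3) median absolute deviation from the row-median
    pseudo-reference.  A sample failing >= 2 Tukey fences is removed.
    """
    m = X.n_samples
    if m < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    values = X.values
    if np.isnan(values).any():
        raise ValueError("outlier detection requires complete values")

    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    distance_score = dist.sum(axis=1) / (m - 1)

    pooled = values.ravel()
    ks_score = np.array(
        [
            sps.ks_2samp(values[:, j], pooled, method="asymp").statistic
            for j in range(m)
        ]
    )

    reference = np.median(values, axis=1)
    deviation_score = np.median(np.abs(values - reference[:, None]), axis=0)

    flags = np.column_stack(
        [
            _tukey_flags(distance_score),
            _tukey_flags(ks_score),
            _tukey_flags(deviation_score),
        ]
    )
    removed = flags.sum(axis=1) >= 2
    return OutlierReport(
        list(X.sample_ids), distance_score, ks_score, deviation_score, flags, removed
    )


def drop_outlier_samples(
    X: ExpressionMatrix, log: RemovalLog | None = None
) -> tuple[ExpressionMatrix, OutlierReport]:
    report = detect_outlier_samples(X)
    bad = set(report.removed_samples())
    if log is not None:
        for s in bad:
            log.record(s, "outlier_sample")
    keep = [s for s in X.sample_ids if s not in bad]
    return X.subset_samples(keep), report


def drop_ambiguous_probes(
    X: ExpressionMatrix, pmap: ProbeGeneMap, log: RemovalLog | None = None
) -> ExpressionMatrix:
    """Keep exactly the rows whose probe maps to exactly one gene."""
    keep = []
    for probe in X.gene_ids:
        n = len(pmap.genes_for(probe))
        if n == 1:
            keep.append(probe)
        elif log is not None:
            log.record(probe, "unmapped_probe" if n == 0 else "ambiguous_probe")
    if not keep:
        warnings.warn("no unambiguous probes remain", stacklevel=2)
    return X.subset_genes(keep)
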