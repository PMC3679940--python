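"""Readers and writers for every on-disk artifact.

All exchange formats are plain text: TSV for matrices, edge lists, probe
maps, sample metadata, partitions and module assignments; GMT for gene
sets.  Read followed by write is the identity for every type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .network_build import CoexpressionNetwork

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "ProbeGeneMap",
    "AnnotationSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_annotations_gmt",
    "write_annotations_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_module_assignments",
    "write_module_assignments",
    "read_partition_tsv",
    "write_partition_tsv",
]


def _check_unique(ids: Iterable[str], axis: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {axis} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (log-scale) expression values.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``; missing measurements are ``NaN``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep_set]
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[j] for j in idx], self.values[:, idx]
        )


@dataclass
class SampleMetadata:
    """Per-sample series membership and free-text description."""

    records: dict[str, tuple[str, str]] = field(default_factory=dict)
    # sample_id -> (series_id, description)

    def add(self, sample_id: str, series_id: str, description: str) -> None:
        if sample_id in self.records:
            raise ValueError(f"duplicate sample identifier: {sample_id!r}")
        self.records[sample_id] = (series_id, description)

    def series_of(self, sample_id: str) -> str:
        return self.records[sample_id][0]

    def description_of(self, sample_id: str) -> str:
        return self.records[sample_id][1]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ProbeGeneMap:
    """Map from probe identifier to the set of genes it may hybridize to.

    Empty sets mark unmapped probes; sets of size > 1 mark ambiguous ones.
    """

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def genes_for(self, probe: str) -> frozenset[str]:
        return self.mapping.get(probe, frozenset())

    def is_unambiguous(self, probe: str) -> bool:
        return len(self.genes_for(probe)) == 1

    def unique_gene(self, probe: str) -> str:
        genes = self.genes_for(probe)
        if len(genes) != 1:
            raise KeyError(f"probe {probe!r} does not map to exactly one gene")
        return next(iter(genes))


@dataclass
class AnnotationSet:
    """Functional terms from one vocabulary, each with a gene set."""

    vocabulary: str
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    # term_id -> (description, genes)

    def add(self, term_id: str, description: str, genes: Iterable[str]) -> None:
        if term_id in self.terms:
            raise ValueError(
                f"duplicate term {term_id!r} in vocabulary {self.vocabulary!r}"
            )
        gene_set = frozenset(genes)
        self.terms[term_id] = (description, gene_set)

    def genes_for(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def description_for(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path, missing_token: str = "NA") -> ExpressionMatrix:
    """Read a TSV matrix with a sample-id header row and gene-id first column."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = _check_unique(cols[1:], "sample")
        n_cols = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            rows.append(
                [math.nan if f == missing_token else float(f) for f in fields[1:]]
            )
    values = np.array(rows, dtype=float) if rows else np.empty((0, n_cols))
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(
    X: ExpressionMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["gene_id", *X.sample_ids]) + "\n")
        for gid, row in zip(X.gene_ids, X.values):
            cells = [missing_token if math.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([gid, *cells]) + "\n")


# ---------------------------------------------------------------------------
# probe -> gene maps ("probe<TAB>gene", one row per mapping)


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            probe, gene = fields
            genes = mapping.setdefault(probe, set())
            if gene:  # empty gene field records an unmapped probe
                genes.add(gene)
    return ProbeGeneMap({p: frozenset(g) for p, g in mapping.items()})


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for probe in sorted(pmap.mapping):
            genes = sorted(pmap.mapping[probe])
            if not genes:
                fh.write(f"{probe}\t\n")
            for gene in genes:
                fh.write(f"{probe}\t{gene}\n")


# ---------------------------------------------------------------------------
# sample metadata ("sample_id<TAB>series_id<TAB>description")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    meta = SampleMetadata()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 fields")
            sample_id, series_id = fields[0], fields[1]
            description = fields[2] if len(fields) > 2 else ""
            meta.add(sample_id, series_id, description)
    return meta


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample_id, (series_id, description) in meta.records.items():
            fh.write(f"{sample_id}\t{series_id}\t{description}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_annotations_gmt(path: str | Path, vocabulary: str) -> AnnotationSet:
    """Read ``term<TAB>description<TAB>gene1<TAB>gene2...`` lines.

    Duplicate genes within one line are deduplicated; an empty file yields
    an empty :class:`AnnotationSet`.
    """
    annot = AnnotationSet(vocabulary)
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            annot.add(fields[0], fields[1], [g for g in fields[2:] if g])
    return annot


def write_annotations_gmt(annot: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term_id, (description, genes) in annot.terms.items():
            fh.write("\t".join([term_id, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# edge lists ("gene_a<TAB>gene_b<TAB>r", gene_a < gene_b)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-edge on {a!r}")
    return (a, b) if a < b else (b, a)


def write_edge_list(network: "CoexpressionNetwork", path: str | Path) -> None:
    """Write one row per unique unordered pair, canonically ordered.

    An empty network produces an empty file (no header), which reads back
    as an empty edge list.
    """
    rows = sorted(
        (canonical_pair(a, b) + (r,)) for a, b, r in network.edges
    )
    with Path(path).open("w") as fh:
        for a, b, r in rows:
            fh.write(f"{a}\t{b}\t{r:.6g}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    edges: list[tuple[str, str, float]] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            a, b = canonical_pair(fields[0], fields[1])
            edges.append((a, b, float(fields[2])))
    return edges


# ---------------------------------------------------------------------------
# module assignments ("module_id<TAB>gene_id")


def write_module_assignments(
    modules: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for module_id in modules:
            for gene in sorted(modules[module_id]):
                fh.write(f"{module_id}\t{gene}\n")


def read_module_assignments(path: str | Path) -> dict[str, set[str]]:
    modules: dict[str, set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            modules.setdefault(fields[0], set()).add(fields[1])
    return modules


# ---------------------------------------------------------------------------
# sample partitions ("sample_id<TAB>cluster")


def write_partition_tsv(assignment: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample_id, cluster in assignment.items():
            fh.write(f"{sample_id}\t{cluster}\n")


def read_partition_tsv(path: str | Path) -> dict[str, int]:
    assignment: dict[str, int] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            if fields[0] in assignment:
                raise ValueError(f"{path}:{lineno}: duplicate sample {fields[0]!r}")
            assignment[fields[0]] = int(fields[1])
    return assignment
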