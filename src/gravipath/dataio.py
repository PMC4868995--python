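"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: GCT v1.2 expression matrices, categorical CLS phenotype
labels, GMT gene-set collections (MSigDB dialect), and tab-separated
protein-protein interaction edge lists.  All parsers accept UTF-8 text with
Unix or Windows line endings, never reorder records, and raise
:class:`FormatError` with a line number on malformed input.

Gene identifiers are opaque, case-sensitive strings; matching between an
expression matrix and a gene-set collection is exact-string matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionDataset",
    "PhenotypeLabels",
    "GeneSet",
    "GeneSetCollection",
    "PPIEdgeList",
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
]


class FormatError(ValueError):
    """A file violates its format contract (message names the line)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with optional per-gene descriptions.

    Rows are genes, columns are samples; values are expression intensities in
    arbitrary linear units.  ``nonnegative`` is True only when every entry is
    >= 0 (the precondition for NMF clustering downstream).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    descriptions: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.descriptions is not None and len(self.descriptions) != len(
            self.gene_ids
        ):
            raise ValueError("descriptions length must match gene count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def nonnegative(self) -> bool:
        """Positivity flag: True iff every entry is >= 0."""
        return bool(np.all(self.values >= 0))

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Row-subset in the given order; unknown ids raise KeyError."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene id not in dataset: {exc.args[0]!r}") from None
        desc = (
            [self.descriptions[i] for i in rows]
            if self.descriptions is not None
            else None
        )
        return ExpressionDataset(
            list(gene_ids), list(self.sample_ids), self.values[rows], desc
        )


@dataclass
class PhenotypeLabels:
    """Per-sample class labels for a two-phenotype design.

    ``class_names`` gives exactly two names in declaration order; the first
    class is treated as the test condition (e.g. microgravity) and the second
    as the reference (e.g. 1g) by the ranking metric.
    """

    labels: list[str]
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.class_names) != 2:
            raise ValueError("exactly two phenotype classes are supported")
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels not among class names: {sorted(unknown)}")
        for name in self.class_names:
            if self.labels.count(name) < 2:
                raise ValueError(
                    f"class {name!r} has fewer than 2 samples; a standard "
                    "deviation over replicates is required"
                )

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def indices(self, class_name: str) -> np.ndarray:
        """Column indices of the samples in the given class."""
        if class_name not in self.class_names:
            raise KeyError(class_name)
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab == class_name]
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """Named gene sets tagged with a module category (hallmark, canonical
    pathways, cancer modules, ...)."""

    sets: list[GeneSet]
    module: str = "unlabeled"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise ValueError(f"duplicate gene-set name: {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


class PPIEdgeList:
    """Undirected weighted edges with confidence scores in [0, 1].

    Edges are stored under a canonical (min, max) key so that lookup is
    symmetric; duplicate edges keep the maximum score; self-loops are
    rejected.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self._edges: dict[tuple[str, str], float] = {}
        for a, b, score in edges:
            self.add(a, b, score)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1] for edge {a}-{b}")
        key = self._key(a, b)
        self._edges[key] = max(score, self._edges.get(key, 0.0))

    def score(self, a: str, b: str) -> float | None:
        return self._edges.get(self._key(a, b))

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return ((a, b, s) for (a, b), s in self._edges.items())

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return out


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------


def read_gct(path: str | Path) -> ExpressionDataset:
    """Parse a GCT v1.2 expression matrix.

    Layout: line 1 the version tag ``#1.2``; line 2 ``<n_rows>\\t<n_cols>``;
    line 3 ``NAME  DESCRIPTION  <sample ids...>``; then one row per gene.
    Gene and sample order are preserved exactly as in the file.
    """
    lines = _read_lines(path)
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1: expected GCT version tag '#1.2'")
    try:
        n_rows, n_cols = (int(tok) for tok in lines[1].split())
    except (IndexError, ValueError):
        raise FormatError(
            f"{path}: line 2: expected '<n_rows> <n_cols>'"
        ) from None
    header = lines[2].split("\t") if len(lines) > 2 else []
    if len(header) < 2 + n_cols:
        raise FormatError(
            f"{path}: line 3: expected NAME, DESCRIPTION and {n_cols} "
            "sample ids"
        )
    sample_ids = header[2 : 2 + n_cols]

    gene_ids: list[str] = []
    descriptions: list[str] = []
    rows: list[list[float]] = []
    body = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: header declares {n_rows} rows but file has {len(body)}"
        )
    for offset, line in enumerate(body):
        lineno = 4 + offset
        fields = line.split("\t")
        if len(fields) != 2 + n_cols:
            raise FormatError(
                f"{path}: line {lineno}: expected {2 + n_cols} fields, "
                f"got {len(fields)}"
            )
        gene_ids.append(fields[0])
        descriptions.append(fields[1])
        try:
            rows.append([float(v) for v in fields[2:]])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric expression value"
            ) from None
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dup = next(g for g in gene_ids if g in seen or seen.add(g))
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return ExpressionDataset(
        gene_ids, sample_ids, np.array(rows, dtype=float), descriptions
    )


def write_gct(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as GCT v1.2, re-readable by :func:`read_gct`."""
    desc = dataset.descriptions or ["na"] * dataset.n_genes
    lines = ["#1.2", f"{dataset.n_genes}\t{dataset.n_samples}"]
    lines.append("\t".join(["NAME", "DESCRIPTION", *dataset.sample_ids]))
    for gid, d, row in zip(dataset.gene_ids, desc, dataset.values):
        lines.append("\t".join([gid, d, *(repr(float(v)) for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CLS (categorical)
# ---------------------------------------------------------------------------


def read_cls(path: str | Path) -> PhenotypeLabels:
    """Parse a categorical CLS phenotype file (two-class designs only).

    Both the symbolic dialect (labels repeat the class names) and the numeric
    dialect (0/1 mapped to class names in declaration order) are accepted.
    """
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if len(lines) < 3:
        raise FormatError(f"{path}: a CLS file needs 3 non-empty lines")
    head = lines[0].split()
    if len(head) != 3:
        raise FormatError(
            f"{path}: line 1: expected '<n_samples> <n_classes> 1'"
        )
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except ValueError:
        raise FormatError(f"{path}: line 1: non-integer counts") from None
    if n_classes != 2:
        raise FormatError(
            f"{path}: {n_classes} classes declared; only two-phenotype "
            "designs are supported"
        )
    name_line = lines[1].split()
    if not name_line or name_line[0] != "#":
        raise FormatError(f"{path}: line 2: expected '# <name> <name>'")
    class_names = tuple(name_line[1:])
    if len(class_names) != 2:
        raise FormatError(
            f"{path}: line 2: expected exactly 2 class names, "
            f"got {len(class_names)}"
        )
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: line 3: header declares {n_samples} samples but "
            f"{len(tokens)} labels are present"
        )
    if set(tokens) <= {"0", "1"}:
        labels = [class_names[int(t)] for t in tokens]
    else:
        unknown = set(tokens) - set(class_names)
        if unknown:
            raise FormatError(
                f"{path}: line 3: labels {sorted(unknown)} not among the "
                f"declared class names {list(class_names)}"
            )
        labels = list(tokens)
    return PhenotypeLabels(labels, class_names)  # type: ignore[arg-type]


def write_cls(labels: PhenotypeLabels, path: str | Path) -> None:
    lines = [
        f"{labels.n_samples} 2 1",
        "# " + " ".join(labels.class_names),
        " ".join(labels.labels),
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, module_label: str = "unlabeled") -> GeneSetCollection:
    """Parse an MSigDB-style GMT gene-set file.

    Each line: set name, description, then member gene ids, tab-separated.
    Duplicate members within a set are de-duplicated (order-preserving) with
    a logged warning; sets left empty are dropped with a warning; duplicate
    set names are an error.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    for offset, line in enumerate(_read_lines(path)):
        if line.strip() == "":
            continue
        lineno = offset + 1
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: expected name, description and at "
                "least one gene id"
            )
        name, description = fields[0], fields[1]
        if name in names:
            raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        names.add(name)
        members: list[str] = []
        seen: set[str] = set()
        for g in fields[2:]:
            if g == "":
                continue
            if g in seen:
                logger.warning(
                    "%s: line %d: duplicate member %r in set %r dropped",
                    path, lineno, g, name,
                )
                continue
            seen.add(g)
            members.append(g)
        if not members:
            logger.warning("%s: line %d: empty set %r dropped", path, lineno, name)
            continue
        sets.append(GeneSet(name, description, tuple(members)))
    return GeneSetCollection(sets, module=module_label)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *s.genes]) for s in collection.sets
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> PPIEdgeList:
    """Parse a tab-separated edge list: gene_a, gene_b, confidence score.

    Self-loops are dropped with a warning; duplicate undirected edges are
    collapsed keeping the maximum score; a score outside [0, 1] is an error.
    """
    out = PPIEdgeList()
    for offset, line in enumerate(_read_lines(path)):
        if line.strip() == "":
            continue
        lineno = offset + 1
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: expected gene_a, gene_b, score"
            )
        a, b = fields[0], fields[1]
        try:
            score = float(fields[2])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric score {fields[2]!r}"
            ) from None
        if not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{path}: line {lineno}: score {score} outside [0, 1]"
            )
        if a == b:
            logger.warning("%s: line %d: self-loop on %r dropped", path, lineno, a)
            continue
        out.add(a, b, score)
    return out


def write_edge_list(edges: PPIEdgeList, path: str | Path) -> None:
    lines = [f"{a}\t{b}\t{s:g}" for a, b, s in sorted(edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
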