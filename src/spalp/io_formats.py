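"""Readers/writers for the pipeline's external text formats.

All formats are plain tab-separated text:

* association list: two columns ``miRNA<TAB>disease``, optional header;
* disease DAG: edge list ``parent<TAB>child``; an isolated node may be
  declared as ``node<TAB>-``;
* similarity matrix: square numeric TSV with a header row and a leading
  name column.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def _normalize_name(name: str) -> str:
    """Collapse internal whitespace and strip the ends."""
    return _WS.sub(" ", name.strip())


@dataclass(frozen=True)
class AssociationCatalog:
    """Named miRNA/disease universes plus the known positive pairs."""

    mirna_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    positive_pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.mirna_names)) != len(self.mirna_names):
            raise ValueError("duplicate miRNA names in catalog")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names in catalog")
        n, m = len(self.mirna_names), len(self.disease_names)
        for i, j in self.positive_pairs:
            if not (0 <= i < n and 0 <= j < m):
                raise ValueError(f"pair index ({i}, {j}) out of range for {n}x{m}")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    def disease_index(self, name: str) -> int:
        try:
            return self.disease_names.index(name)
        except ValueError:
            raise KeyError(f"unknown disease: {name!r}") from None


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary miRNA x disease matrix; 1 marks a known association."""

    values: np.ndarray
    row_names: tuple[str, ...]
    col_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError("adjacency shape does not match name lists")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.int8))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    names: tuple[str, ...]
    atol: float = field(default=1e-9, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("similarity matrix has non-finite entries")
        if v.size and (v.min() < -self.atol or v.max() > 1 + self.atol):
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.allclose(v, v.T, atol=self.atol, rtol=0):
            raise ValueError("similarity matrix is asymmetric beyond tolerance")
        if not np.allclose(np.diag(v), 1.0, atol=self.atol, rtol=0):
            raise ValueError("similarity diagonal must be 1")
        object.__setattr__(self, "values", v)


class ParseError(ValueError):
    """A file violated its expected grammar."""


def _read_two_column_tsv(path: str | Path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields in "
                    f"{what}, got {len(fields)}"
                )
            rows.append((fields[0], fields[1]))
    if not rows:
        raise ParseError(f"{path}: empty {what}")
    return rows


def read_association_list(path: str | Path) -> AssociationCatalog:
    """Parse a two-column miRNA/disease TSV into a catalog.

    Names are deduplicated preserving first-seen order. Disease names are
    matched case-insensitively after whitespace normalization; every fold
    is logged. Duplicate pairs are collapsed with a warning. A header line
    whose fields look like column titles (``mirna``/``disease``) is skipped.
    """
    rows = _read_two_column_tsv(path, "association list")
    first = tuple(f.strip().lower() for f in rows[0])
    if first[0] in {"mirna", "mir", "name"} or first[1] in {"disease", "diseases"}:
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: association list has a header but no data")

    mirna_index: dict[str, int] = {}
    mirna_names: list[str] = []
    disease_index: dict[str, int] = {}  # keyed by casefolded form
    disease_names: list[str] = []
    pairs: set[tuple[int, int]] = set()
    for mirna_raw, disease_raw in rows:
        mirna = _normalize_name(mirna_raw)
        disease = _normalize_name(disease_raw)
        if not mirna or not disease:
            raise ParseError(f"{path}: empty miRNA or disease name")
        if mirna not in mirna_index:
            mirna_index[mirna] = len(mirna_names)
            mirna_names.append(mirna)
        key = disease.casefold()
        if key not in disease_index:
            disease_index[key] = len(disease_names)
            disease_names.append(disease)
        elif disease != disease_names[disease_index[key]]:
            logger.info(
                "folding disease name %r onto first-seen form %r",
                disease,
                disease_names[disease_index[key]],
            )
        pair = (mirna_index[mirna], disease_index[key])
        if pair in pairs:
            logger.warning("duplicate association %s / %s collapsed", mirna, disease)
        pairs.add(pair)
    return AssociationCatalog(
        mirna_names=tuple(mirna_names),
        disease_names=tuple(disease_names),
        positive_pairs=frozenset(pairs),
    )


def write_association_list(catalog: AssociationCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(catalog.positive_pairs):
            fh.write(f"{catalog.mirna_names[i]}\t{catalog.disease_names[j]}\n")


def build_adjacency(catalog: AssociationCatalog) -> AdjacencyMatrix:
    """Materialize the binary association matrix MD from a catalog."""
    md = np.zeros((catalog.n_mirnas, catalog.n_diseases), dtype=np.int8)
    for i, j in catalog.positive_pairs:
        md[i, j] = 1
    return AdjacencyMatrix(
        values=md, row_names=catalog.mirna_names, col_names=catalog.disease_names
    )


def extract_catalog(adjacency: AdjacencyMatrix) -> AssociationCatalog:
    """Inverse of :func:`build_adjacency`."""
    rows, cols = np.nonzero(adjacency.values)
    return AssociationCatalog(
        mirna_names=adjacency.row_names,
        disease_names=adjacency.col_names,
        positive_pairs=frozenset(zip(rows.tolist(), cols.tolist())),
    )


def read_dag(path: str | Path):
    """Read a ``parent<TAB>child`` edge list into a :class:`DiseaseDAG`.

    A line ``node<TAB>-`` declares an isolated node. Cycles are rejected
    with one offending cycle in the message.
    """
    from .similarity import DiseaseDAG

    rows = _read_two_column_tsv(path, "DAG edge list")
    parents: dict[str, set[str]] = {}
    for parent_raw, child_raw in rows:
        parent = _normalize_name(parent_raw)
        child = _normalize_name(child_raw)
        if not parent:
            raise ParseError(f"{path}: empty node name in DAG edge list")
        if child == "-":
            parents.setdefault(parent, set())
            continue
        if not child:
            raise ParseError(f"{path}: empty node name in DAG edge list")
        parents.setdefault(parent, set())
        parents.setdefault(child, set()).add(parent)
    return DiseaseDAG(parents=parents)


def write_dag(dag, path: str | Path) -> None:
    """Write a DAG as a ``parent<TAB>child`` edge list (isolated: ``node<TAB>-``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(dag.nodes):
            node_parents = sorted(dag.parents[node])
            for parent in node_parents:
                fh.write(f"{parent}\t{node}\n")
        for node in sorted(dag.nodes):
            if not dag.parents[node] and not dag.children(node):
                fh.write(f"{node}\t-\n")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labelled square TSV; validates symmetry, range and diagonal."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty similarity matrix")
    header = lines[0].split("\t")
    if header and header[0] == "":
        header = header[1:]
    names = tuple(header)
    n = len(names)
    if len(lines) - 1 != n:
        raise ParseError(
            f"{path}: non-square similarity matrix ({n} columns, {len(lines) - 1} rows)"
        )
    values = np.empty((n, n), dtype=float)
    for r, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ParseError(f"{path}: row {r + 1} has {len(fields) - 1} values, expected {n}")
        if fields[0] != names[r]:
            raise ParseError(
                f"{path}: row label {fields[0]!r} does not match column label {names[r]!r}"
            )
        try:
            values[r] = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric entry in row {r + 1}: {exc}") from exc
    try:
        return SimilarityMatrix(values=values, names=names)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write with 17 significant digits so write -> read round-trips exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.names) + "\n")
        for name, row in zip(matrix.names, matrix.values):
            fh.write(name + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def write_ranking(entries: Iterable[tuple[int, str, float]], path: str | Path) -> None:
    """Write a ranked prediction table as ``rank<TAB>miRNA<TAB>score``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmirna\tscore\n")
        for rank, name, score in entries:
            fh.write(f"{rank}\t{name}\t{score:.17g}\n")


def write_pair_samples(
    pairs: Sequence[tuple[int, int]],
    labels: Sequence[int],
    catalog: AssociationCatalog,
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tdisease\tlabel\n")
        for (i, j), y in zip(pairs, labels):
            fh.write(f"{catalog.mirna_names[i]}\t{catalog.disease_names[j]}\t{int(y)}\n")
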