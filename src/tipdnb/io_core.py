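"""Domain containers and readers/writers for the pipeline's on-disk formats.

Every stage of the pipeline consumes and produces the same small set of
plain-text formats: a gene × sample expression TSV, a two-column sample
design TSV mapping samples to ordered condition groups, and Broad-dialect
GMT files for gene sets.  The containers here validate the invariants the
downstream statistics rely on (unique identifiers, a reference group, a
consistent design) once, at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["counts", "log2"]


class FormatError(ValueError):
    """A file does not conform to the expected plain-text format."""


class DesignError(ValueError):
    """The sample design is inconsistent with the expression matrix."""


@dataclass(frozen=True)
class SampleDesign:
    """Maps samples to ordered condition groups.

    ``group_order[0]`` is the reference condition by definition: every
    contrast in the pipeline (differential expression, SD-fold selection,
    ΔΔCt) is taken against it.
    """

    sample_to_group: dict[str, str]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.group_order) < 2:
            raise DesignError("design needs at least 2 groups (reference + 1)")
        if len(set(self.group_order)) != len(self.group_order):
            raise DesignError("duplicate group label in group_order")
        used = set(self.sample_to_group.values())
        declared = set(self.group_order)
        if used - declared:
            raise DesignError(f"groups not in group_order: {sorted(used - declared)}")
        if declared - used:
            raise DesignError(f"groups without samples: {sorted(declared - used)}")

    @property
    def reference(self) -> str:
        return self.group_order[0]

    def samples_of(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise DesignError(f"unknown group {group!r}")
        return [s for s, g in self.sample_to_group.items() if g == group]

    def replicates(self, group: str) -> int:
        return len(self.samples_of(group))


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with an ordered group design.

    ``values`` is genes (rows) × samples (columns).  ``scale`` records
    whether cells are raw counts (finite, ≥ 0) or log2-scale reals; stages
    that require one scale refuse the other rather than silently converting.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    design: SampleDesign
    scale: Scale = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.gene_ids:
            raise FormatError("matrix must contain at least one gene")
        if not self.sample_ids:
            raise FormatError("matrix must contain at least one sample")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample id {dup!r}")
        if any(not g for g in self.gene_ids) or any(not s for s in self.sample_ids):
            raise FormatError("empty identifier")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression value")
        if self.scale == "counts" and np.any(self.values < 0):
            raise FormatError("negative value in counts-scale matrix")
        missing = [s for s in self.sample_ids if s not in self.design.sample_to_group]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")
        extra = [s for s in self.design.sample_to_group if s not in set(self.sample_ids)]
        if extra:
            raise DesignError(f"design samples missing from matrix: {extra}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def columns_of(self, group: str) -> np.ndarray:
        """Column indices of the given group, in matrix order."""
        members = set(self.design.samples_of(group))
        return np.array([i for i, s in enumerate(self.sample_ids) if s in members], dtype=int)

    def group_values(self, group: str) -> np.ndarray:
        """genes × replicates sub-matrix for one group."""
        return self.values[:, self.columns_of(group)]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneSetCollection:
    """Named gene sets, as carried by GMT files."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"duplicate gene within set {name!r}")

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# Expression / design TSV


def read_design_tsv(path: str | Path) -> SampleDesign:
    """Read a sample design TSV with columns ``sample_id`` and ``group``.

    Group order may be declared in a header comment line
    ``# group_order: sham,IR16,...``; otherwise groups are ordered by first
    appearance (the first sample's group becomes the reference).
    """
    path = Path(path)
    group_order: tuple[str, ...] | None = None
    rows: list[tuple[str, str]] = []
    header_seen = False
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("group_order:"):
                    labels = body.split(":", 1)[1]
                    group_order = tuple(g.strip() for g in labels.split(",") if g.strip())
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip().lower() for f in fields[:2]] != ["sample_id", "group"]:
                    raise FormatError(
                        f"{path}:{ln}: design header must be 'sample_id\\tgroup'"
                    )
                header_seen = True
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            rows.append((fields[0], fields[1]))
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    dup = _first_duplicate([s for s, _ in rows])
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    if group_order is None:
        seen: list[str] = []
        for _, g in rows:
            if g not in seen:
                seen.append(g)
        group_order = tuple(seen)
    return SampleDesign(sample_to_group=dict(rows), group_order=group_order)


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# group_order: " + ",".join(design.group_order) + "\n")
        fh.write("sample_id\tgroup\n")
        for sample, group in design.sample_to_group.items():
            fh.write(f"{sample}\t{group}\n")


def read_expression_tsv(
    path: str | Path,
    design_path: str | Path,
    scale: Scale = "counts",
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene ids, header of sample ids)
    together with its design TSV, preserving file order of genes and samples.
    """
    path = Path(path)
    design = read_design_tsv(design_path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must contain gene_id column plus samples")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for ln, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{ln}: expected {len(header)} fields, found {len(fields)}"
                )
            gene_ids.append(fields[0])
            row: list[float] = []
            for ci, cell in enumerate(fields[1:], start=2):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{ln}: non-numeric value {cell!r} in column {ci} "
                        f"(sample {sample_ids[ci - 2]!r})"
                    ) from None
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no gene rows")
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        design=design,
        scale=scale,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV at full float precision (repr round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(_fmt_float(v) for v in row) + "\n")


def _fmt_float(v: float) -> str:
    # repr gives the shortest string that round-trips the double exactly
    if v == math.floor(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB gene TAB gene ...

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a duplicate set name is a hard error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs ≥ 3 fields (name, description, gene...)")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
            deduped: list[str] = []
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    logger.warning("%s:%d: duplicate gene %r in set %r dropped", path, ln, g, name)
                    continue
                seen.add(g)
                deduped.append(g)
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def matrix_to_frame(matrix: ExpressionMatrix) -> pd.DataFrame:
    """View the matrix as a pandas DataFrame (genes × samples)."""
    return pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
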