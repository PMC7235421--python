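"""Marker-gene evidence: databases, the cell-gene evidence matrix and the
per-cell-type style vector.

Evidence counts are numbers of supporting references for a (cell type,
gene) pair. Before scoring they are transformed with ``log2(a) + 0.05`` to
damp the gap between famous and obscure markers. The style vector for a
cell type multiplies the population standard deviation of its (transformed)
matched evidence by the number of matched markers; single-marker rows use a
standard-deviation factor of 1 so they remain scoreable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyDatabaseError, FormatError

VALID_SPECIES = ("human", "mouse")

REFERENCE_COLUMNS = ("species", "tissue", "cell_type", "gene_symbol", "ref_count")


@dataclass
class MarkerDatabase:
    """One source of marker evidence.

    ``entries`` maps (cell type, gene symbol) to the evidence count ``a``
    (number of supporting references, >= 1), aggregated over tissues.
    """

    name: str
    entries: dict[tuple[str, str], int] = field(default_factory=dict)
    species: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        for (cell_type, gene), count in self.entries.items():
            if count < 1:
                raise FormatError(
                    f"database {self.name!r}: evidence count {count} for "
                    f"({cell_type!r}, {gene!r}) must be >= 1"
                )
            if not cell_type:
                raise FormatError(f"database {self.name!r}: empty cell-type name")

    def cell_types(self) -> list[str]:
        return sorted({ct for ct, _ in self.entries})

    def genes(self) -> set[str]:
        return {g for _, g in self.entries}

    def markers_of(self, cell_type: str) -> dict[str, int]:
        return {
            g: a for (ct, g), a in self.entries.items() if ct == cell_type
        }


@dataclass
class EvidenceMatrix:
    """Cell-type x gene matrix of transformed evidence for one cluster.

    Rows are candidate cell types (each with at least one matched marker),
    columns follow the cluster's filtered DEG gene order. Entries are
    ``log2(a) + 0.05`` where the gene is a marker of the cell type, else 0.
    """

    cell_types: list[str]
    genes: list[str]
    values: np.ndarray

    @property
    def is_empty(self) -> bool:
        return len(self.cell_types) == 0 or len(self.genes) == 0


@dataclass
class StyleVector:
    """Per-cell-type style factor l, aligned to an EvidenceMatrix's rows."""

    cell_types: list[str]
    values: np.ndarray


def evidence_transform(a: int | float) -> float:
    """Transform a raw evidence count: ``log2(a) + 0.05``."""
    if a < 1:
        raise ValueError(f"evidence count must be >= 1, got {a!r}")
    return math.log2(a) + 0.05


def load_reference_db(
    path: str | Path,
    species: str,
    tissue_filter: list[str] | None = None,
    name: str = "reference",
    weight: float = 1.0,
) -> MarkerDatabase:
    """Load a reference marker table (CellMarker-like schema).

    The table is a delimited text file with columns ``species``, ``tissue``,
    ``cell_type``, ``gene_symbol``, ``ref_count``. The evidence count for a
    (cell type, gene) pair is the sum of ``ref_count`` over all matching
    rows (across tissues unless ``tissue_filter`` restricts them).
    """
    if species not in VALID_SPECIES:
        raise ConfigError(
            f"unknown species {species!r}; expected one of {VALID_SPECIES}"
        )
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing reference columns {missing}")
    df = df[df["species"].astype(str).str.strip().str.lower() == species]
    if tissue_filter:
        wanted = {t.strip().lower() for t in tissue_filter}
        df = df[df["tissue"].astype(str).str.strip().str.lower().isin(wanted)]
    if df.empty:
        raise EmptyDatabaseError(
            f"{path}: no entries left for species={species!r} "
            f"tissue_filter={tissue_filter!r}"
        )
    entries: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        cell_type = str(row["cell_type"]).strip()
        gene = str(row["gene_symbol"]).strip().strip("'\"").upper()
        count = int(row["ref_count"])
        if count < 1:
            raise FormatError(
                f"{path}: ref_count must be >= 1 for ({cell_type}, {gene})"
            )
        key = (cell_type, gene)
        entries[key] = entries.get(key, 0) + count
    return MarkerDatabase(name=name, entries=entries, species=species, weight=weight)


def packaged_reference_path() -> Path:
    """Path of the small marker reference table shipped with the package."""
    return Path(
        resources.files("cellanno").joinpath("data/reference_markers.tsv")
    )


def build_evidence_matrix(
    db: MarkerDatabase, cluster_genes: list[str]
) -> EvidenceMatrix:
    """Build the evidence matrix for one cluster against one database.

    Columns are the cluster genes that appear in the database (cluster
    order preserved); rows are the cell types with at least one such
    marker, sorted by name for determinism. An empty intersection yields an
    empty matrix, signalling "no marker evidence" to the caller.
    """
    db_genes = db.genes()
    seen: dict[str, None] = {}
    for g in cluster_genes:
        if g in db_genes:
            seen.setdefault(g, None)
    genes = list(seen)
    if not genes:
        return EvidenceMatrix([], [], np.zeros((0, 0)))
    gene_index = {g: j for j, g in enumerate(genes)}
    hits: dict[str, dict[int, float]] = {}
    for (cell_type, gene), count in db.entries.items():
        j = gene_index.get(gene)
        if j is not None:
            hits.setdefault(cell_type, {})[j] = evidence_transform(count)
    cell_types = sorted(hits)
    values = np.zeros((len(cell_types), len(genes)))
    for i, cell_type in enumerate(cell_types):
        for j, v in hits[cell_type].items():
            values[i, j] = v
    return EvidenceMatrix(cell_types, genes, values)


def style_vector(matrix: EvidenceMatrix) -> StyleVector:
    """Compute l = std(nonzero evidence) * num(nonzero evidence) per row.

    The standard deviation is the population form over the row's nonzero
    entries only. A single-marker row would be zeroed by the literal
    formula, so its std factor is replaced by 1, giving l = 1.
    """
    if matrix.is_empty:
        raise ValueError("cannot compute a style vector for an empty matrix")
    out = np.zeros(len(matrix.cell_types))
    for i in range(matrix.values.shape[0]):
        row = matrix.values[i]
        nonzero = row[row > 0]
        num = nonzero.size
        std_factor = 1.0 if num == 1 else float(np.std(nonzero))
        out[i] = std_factor * num
    return StyleVector(list(matrix.cell_types), out)
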