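"""Readers and writers for every external table the tool touches.

Supported dialects:

* CellRanger differential-expression CSV: first two columns are gene id and
  gene name, followed by per-cluster column triplets
  ``Cluster <label> Mean Counts`` / ``Cluster <label> Log2 fold change`` /
  ``Cluster <label> Adjusted p value``.
* Seurat ``FindAllMarkers`` CSV: long format with ``p_val``,
  ``avg_log2FC`` (or the older ``avg_logFC``), ``cluster``, ``gene`` and
  optionally ``p_val_adj`` columns.
* Two-column user marker database (cell type, gene), TSV or CSV.
* Two/three-column gene-to-term map (gene, term[, term name]).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyInputError, FormatError
from .marker_database import MarkerDatabase

logger = logging.getLogger(__name__)

_HEADER_WORDS = {
    "gene", "genes", "marker", "markers", "symbol", "gene_symbol",
    "genesymbol", "marker_gene", "markergene",
}

_SYMBOL_RE = re.compile(r"[A-Za-z0-9._\-]+")


def normalize_gene(symbol: str) -> str:
    """Canonical gene symbol: strip whitespace/quotes, uppercase."""
    return symbol.strip().strip("'\"").strip().upper()


@dataclass(frozen=True)
class DEGRecord:
    """One differential-expression observation for a gene in a cluster."""

    gene: str
    cluster: str
    lfc: float
    pvalue: float
    mean_expr: float | None = None

    def __post_init__(self) -> None:
        gene = normalize_gene(self.gene)
        if not gene:
            raise FormatError("gene symbol empty after normalization")
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "cluster", str(self.cluster).strip())
        if not (0.0 <= self.pvalue <= 1.0):
            raise FormatError(
                f"p-value {self.pvalue!r} for gene {gene!r} outside [0, 1]"
            )


@dataclass
class DEGTable:
    """Deduplicated collection of :class:`DEGRecord`.

    Duplicate (gene, cluster) rows keep the record with maximum ``|lfc|``,
    ties broken by smaller p-value, then by first occurrence.
    """

    records: list[DEGRecord] = field(default_factory=list)
    source_dialect: str = "generic"

    @classmethod
    def from_records(
        cls, records: Iterable[DEGRecord], source_dialect: str = "generic"
    ) -> "DEGTable":
        best: dict[tuple[str, str], DEGRecord] = {}
        order: list[tuple[str, str]] = []
        for rec in records:
            key = (rec.gene, rec.cluster)
            if key not in best:
                best[key] = rec
                order.append(key)
                continue
            cur = best[key]
            if (abs(rec.lfc), -rec.pvalue) > (abs(cur.lfc), -cur.pvalue):
                best[key] = rec
        return cls([best[k] for k in order], source_dialect)

    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.cluster, None)
        return list(seen)

    def records_for(self, cluster: str) -> list[DEGRecord]:
        if cluster not in set(self.clusters()):
            raise KeyError(f"unknown cluster label {cluster!r}")
        return [r for r in self.records if r.cluster == cluster]

    def sorted_records(self) -> list[DEGRecord]:
        return sorted(self.records, key=lambda r: (r.cluster, r.gene))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TermMap:
    """Flattened gene-to-term annotation used by the enrichment fallback."""

    mapping: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def terms_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.mapping.items():
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out

    def genes(self) -> set[str]:
        return set(self.mapping)


# ---------------------------------------------------------------------------
# CellRanger dialect
# ---------------------------------------------------------------------------

_CR_COL_RE = re.compile(
    r"^cluster\s+(?P<label>.+?)\s+"
    r"(?P<kind>mean counts|log2 fold change|adjusted p value)$",
    re.IGNORECASE,
)
_CR_KINDS = ("mean counts", "log2 fold change", "adjusted p value")


def read_cellranger_diffexp(path: str | Path) -> DEGTable:
    """Parse a CellRanger differential-expression CSV into a DEGTable."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file is empty") from exc
    cols = list(df.columns)
    if len(cols) < 5:
        raise FormatError(
            f"{path}: expected gene id, gene name and at least one cluster "
            f"triplet, found {len(cols)} columns"
        )
    triplets: dict[str, dict[str, str]] = {}
    for col in cols[2:]:
        m = _CR_COL_RE.match(str(col).strip())
        if m is None:
            raise FormatError(f"{path}: unrecognized column {col!r}")
        triplets.setdefault(m.group("label"), {})[m.group("kind").lower()] = col
    for label, kinds in triplets.items():
        for kind in _CR_KINDS:
            if kind not in kinds:
                raise FormatError(
                    f"{path}: cluster {label!r} is missing its "
                    f"'{kind}' column"
                )
    records: list[DEGRecord] = []
    name_col = cols[1]
    for _, row in df.iterrows():
        symbol = str(row[name_col])
        for label, kinds in triplets.items():
            lfc = row[kinds["log2 fold change"]]
            pval = row[kinds["adjusted p value"]]
            if pd.isna(lfc) or pd.isna(pval):
                continue  # sparse cell: gene not tested in this cluster
            mean = row[kinds["mean counts"]]
            records.append(
                DEGRecord(
                    gene=symbol,
                    cluster=label,
                    lfc=float(lfc),
                    pvalue=float(pval),
                    mean_expr=None if pd.isna(mean) else float(mean),
                )
            )
    return DEGTable.from_records(records, source_dialect="cellranger")


def write_cellranger_diffexp(table: DEGTable, path: str | Path) -> None:
    """Write a DEGTable as a CellRanger-style dense CSV.

    (gene, cluster) pairs absent from the table are left blank so the file
    round-trips through :func:`read_cellranger_diffexp` unchanged.
    """
    path = Path(path)
    clusters = sorted(table.clusters())
    genes: dict[str, None] = {}
    for rec in table.records:
        genes.setdefault(rec.gene, None)
    by_key = {(r.gene, r.cluster): r for r in table.records}
    header = ["Gene ID", "Gene Name"]
    for label in clusters:
        header += [
            f"Cluster {label} Mean Counts",
            f"Cluster {label} Log2 fold change",
            f"Cluster {label} Adjusted p value",
        ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for gene in genes:
            row: list[object] = [gene, gene]
            for label in clusters:
                rec = by_key.get((gene, label))
                if rec is None:
                    row += ["", "", ""]
                else:
                    mean = "" if rec.mean_expr is None else repr(rec.mean_expr)
                    row += [mean, repr(rec.lfc), repr(rec.pvalue)]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Seurat dialect
# ---------------------------------------------------------------------------


def read_seurat_markers(path: str | Path) -> DEGTable:
    """Parse a Seurat FindAllMarkers table (CSV or TSV) into a DEGTable."""
    path = Path(path)
    with path.open() as fh:
        first_line = fh.readline()
    sep = "\t" if "\t" in first_line else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file is empty") from exc
    for required in ("gene", "cluster"):
        if required not in df.columns:
            raise FormatError(f"{path}: missing required column {required!r}")
    if "avg_log2FC" in df.columns:
        lfc_col = "avg_log2FC"
    elif "avg_logFC" in df.columns:
        lfc_col = "avg_logFC"
    else:
        raise FormatError(f"{path}: missing avg_log2FC/avg_logFC column")
    if "p_val_adj" in df.columns:
        p_col = "p_val_adj"
    elif "p_val" in df.columns:
        p_col = "p_val"
    else:
        raise FormatError(f"{path}: missing p_val/p_val_adj column")
    if df.empty:
        logger.warning("%s: no data rows, returning empty DEG table", path)
        return DEGTable([], source_dialect="seurat")
    records = [
        DEGRecord(
            gene=str(row["gene"]),
            cluster=str(row["cluster"]),
            lfc=float(row[lfc_col]),
            pvalue=float(row[p_col]),
        )
        for _, row in df.iterrows()
        if not (pd.isna(row[lfc_col]) or pd.isna(row[p_col]))
    ]
    return DEGTable.from_records(records, source_dialect="seurat")


def write_seurat_markers(table: DEGTable, path: str | Path) -> None:
    """Write a DEGTable in the Seurat FindAllMarkers CSV layout."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["p_val", "avg_log2FC", "cluster", "gene", "p_val_adj"])
        for rec in table.records:
            writer.writerow(
                [repr(rec.pvalue), repr(rec.lfc), rec.cluster, rec.gene,
                 repr(rec.pvalue)]
            )


# ---------------------------------------------------------------------------
# User marker database and term map
# ---------------------------------------------------------------------------


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_delimited(path: Path, delimiter: str | None) -> list[list[str]]:
    delim = _detect_delimiter(path, delimiter)
    with path.open(newline="") as fh:
        return [row for row in csv.reader(fh, delimiter=delim) if any(
            f.strip() for f in row)]


def read_user_marker_db(
    path: str | Path, delimiter: str | None = None
) -> MarkerDatabase:
    """Read a two-column (cell type, marker gene) user database.

    Evidence count is 1 per (cell type, gene) pair, incremented each time
    the same pair is repeated.
    """
    path = Path(path)
    rows = _read_delimited(path, delimiter)
    if not rows:
        raise EmptyInputError(f"{path}: user marker database is empty")
    first = rows[0]
    if len(first) == 2 and not _plausible_symbol(first[1]):
        rows = rows[1:]
        if not rows:
            raise EmptyInputError(
                f"{path}: user marker database has a header but no rows"
            )
    entries: dict[tuple[str, str], int] = {}
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise FormatError(
                f"{path}: line {lineno}: expected 2 fields, got {len(row)}"
            )
        cell_type = row[0].strip()
        gene = normalize_gene(row[1])
        if not cell_type or not gene:
            raise FormatError(f"{path}: line {lineno}: empty field")
        key = (cell_type, gene)
        entries[key] = entries.get(key, 0) + 1
    return MarkerDatabase(name="user", entries=entries)


def _plausible_symbol(token: str) -> bool:
    token = token.strip()
    if token.lower() in _HEADER_WORDS:
        return False
    return _SYMBOL_RE.fullmatch(token) is not None


def read_term_map(path: str | Path, delimiter: str | None = None) -> TermMap:
    """Read a two/three-column (gene, term[, term name]) map."""
    path = Path(path)
    rows = _read_delimited(path, delimiter)
    if rows and rows[0] and rows[0][0].strip().lower() in _HEADER_WORDS:
        rows = rows[1:]
    tm = TermMap()
    for lineno, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise FormatError(
                f"{path}: line {lineno}: expected at least 2 fields, "
                f"got {len(row)}"
            )
        gene = normalize_gene(row[0])
        term = row[1].strip()
        if not gene or not term:
            raise FormatError(f"{path}: line {lineno}: empty field")
        tm.mapping.setdefault(gene, set()).add(term)
        if len(row) >= 3 and row[2].strip():
            tm.term_names[term] = row[2].strip()
    return tm


# ---------------------------------------------------------------------------
# Annotation output
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("cluster", "rank", "cell_type", "uniform_score", "status")


def write_annotation(results: Sequence, path: str | Path) -> None:
    """Write ranked annotations as a deterministic TSV.

    Rows are ordered by cluster label ascending, then rank. Clusters with
    an empty ranking (unresolved) are emitted as a single placeholder row.
    """
    if not results:
        raise ValueError("no annotation results to write")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(ANNOTATION_COLUMNS)
        for res in sorted(results, key=lambda r: r.cluster):
            if not res.ranking:
                writer.writerow([res.cluster, 1, "NA", "NA", res.status])
                continue
            for rank, (cell_type, score) in enumerate(res.ranking, start=1):
                writer.writerow(
                    [res.cluster, rank, cell_type, f"{score:.6f}", res.status]
                )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read back an annotation TSV (convenience for tests/round-trips)."""
    return pd.read_csv(path, sep="\t", dtype={"cluster": str})
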