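"""Synthetic marker databases, DEG tables and expression matrices with
planted ground truth.

Gene names are synthetic tokens (SYNG0001, ...) so they can never collide
with real symbol conventions; all randomness flows through one seeded
generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats_io import DEGRecord, DEGTable, TermMap
from .marker_database import MarkerDatabase


@dataclass
class FixtureSpec:
    n_cell_types: int = 5
    markers_per_type: int = 5
    overlap_fraction: float = 0.0
    evidence_count_range: tuple[int, int] = (1, 10)
    n_clusters: int = 5
    noise_gene_fraction: float = 0.0
    lfc_range: tuple[float, float] = (1.5, 4.0)
    seed: int = 0
    # expression-fixture knobs
    cells_per_cluster: int = 20
    effect_size: float = 3.0
    noise_sd: float = 0.5
    baseline: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ConfigError("n_cell_types must be >= 2")
        if self.markers_per_type < 1:
            raise ConfigError("markers_per_type must be >= 1")
        if not (0 <= self.overlap_fraction < 1):
            raise ConfigError("overlap_fraction must be in [0, 1)")
        lo, hi = self.evidence_count_range
        if not (1 <= lo <= hi):
            raise ConfigError("evidence_count_range must satisfy 1 <= low <= high")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if not (0 <= self.noise_gene_fraction < 1):
            raise ConfigError("noise_gene_fraction must be in [0, 1)")
        lfc_lo, lfc_hi = self.lfc_range
        if not (0 < lfc_lo <= lfc_hi):
            raise ConfigError("lfc_range must satisfy 0 < low <= high")
        if self.cells_per_cluster < 2:
            raise ConfigError("cells_per_cluster must be >= 2")


def _gene_token(i: int) -> str:
    return f"SYNG{i:04d}"


def generate_marker_db(
    spec: FixtureSpec,
) -> tuple[MarkerDatabase, dict[str, list[str]]]:
    """Synthetic database CT1..CTn plus the cell-type -> markers truth map.

    ``floor(overlap_fraction * markers_per_type)`` markers of each type are
    shared with the next type (cyclically); the rest are private.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = math.floor(spec.overlap_fraction * spec.markers_per_type)
    n_own = spec.markers_per_type - n_shared
    if n_own < 1:
        raise ConfigError(
            f"overlap_fraction {spec.overlap_fraction} leaves no private "
            f"markers for {spec.markers_per_type} markers per type"
        )
    own: list[list[str]] = []
    counter = 1
    for _ in range(spec.n_cell_types):
        own.append([_gene_token(counter + i) for i in range(n_own)])
        counter += n_own
    markers: dict[str, list[str]] = {}
    for t in range(spec.n_cell_types):
        borrowed = own[(t + 1) % spec.n_cell_types][:n_shared]
        markers[f"CT{t + 1}"] = own[t] + borrowed
    lo, hi = spec.evidence_count_range
    entries: dict[tuple[str, str], int] = {}
    for cell_type in markers:
        for gene in markers[cell_type]:
            entries[(cell_type, gene)] = int(rng.integers(lo, hi + 1))
    db = MarkerDatabase(name="synthetic", entries=entries, species="human")
    return db, markers


def assign_truth(spec: FixtureSpec) -> dict[str, str]:
    """Cluster label -> planted cell type, round-robin over the types."""
    return {
        str(i): f"CT{(i % spec.n_cell_types) + 1}"
        for i in range(spec.n_clusters)
    }


def generate_deg_table(
    db: MarkerDatabase, truth: dict[str, str], spec: FixtureSpec
) -> DEGTable:
    """DEG table whose per-cluster genes are the true type's markers plus
    optional noise genes (off-target markers or genes absent from the db)."""
    rng = np.random.default_rng(spec.seed + 1)
    lfc_lo, lfc_hi = spec.lfc_range
    all_db_genes = sorted(db.genes())
    records: list[DEGRecord] = []
    fresh_counter = 1
    for cluster in sorted(truth, key=str):
        cell_type = truth[cluster]
        marker_genes = sorted(db.markers_of(cell_type))
        if not marker_genes:
            raise ConfigError(f"planted cell type {cell_type!r} not in database")
        used = set(marker_genes)
        for gene in marker_genes:
            records.append(
                DEGRecord(
                    gene=gene,
                    cluster=cluster,
                    lfc=float(rng.uniform(lfc_lo, lfc_hi)),
                    pvalue=float(rng.uniform(1e-12, 0.01)),
                )
            )
        n_noise = math.floor(spec.noise_gene_fraction * len(marker_genes))
        off_target = [g for g in all_db_genes if g not in used]
        added = 0
        while added < n_noise:
            if off_target and rng.random() < 0.5:
                idx = int(rng.integers(len(off_target)))
                gene = off_target.pop(idx)
            else:
                gene = f"NOIS{fresh_counter:04d}"
                fresh_counter += 1
            if gene in used:
                continue
            used.add(gene)
            records.append(
                DEGRecord(
                    gene=gene,
                    cluster=cluster,
                    lfc=float(rng.uniform(lfc_lo, lfc_hi)),
                    pvalue=float(rng.uniform(1e-12, 0.01)),
                )
            )
            added += 1
    return DEGTable.from_records(records, source_dialect="generic")


def generate_expression(
    db: MarkerDatabase, truth: dict[str, str], spec: FixtureSpec
) -> tuple[pd.DataFrame, list[str]]:
    """Genes x cells expression matrix with planted marker upshifts.

    Marker genes of a cluster's true type are shifted upward by
    ``effect_size`` (log-scale units) on top of Gaussian noise around a
    common baseline.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = sorted(db.genes())
    gene_index = {g: i for i, g in enumerate(genes)}
    clusters = sorted(truth, key=str)
    n_cells = spec.cells_per_cluster * len(clusters)
    matrix = spec.baseline + rng.normal(0.0, spec.noise_sd, (len(genes), n_cells))
    labels: list[str] = []
    for c_idx, cluster in enumerate(clusters):
        start = c_idx * spec.cells_per_cluster
        stop = start + spec.cells_per_cluster
        labels.extend([cluster] * spec.cells_per_cluster)
        for gene in db.markers_of(truth[cluster]):
            matrix[gene_index[gene], start:stop] += spec.effect_size
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    return pd.DataFrame(matrix, index=genes, columns=cells), labels


def generate_term_map(markers: dict[str, list[str]]) -> TermMap:
    """One synthetic term per cell type containing exactly its markers."""
    tm = TermMap()
    for i, (cell_type, genes) in enumerate(sorted(markers.items()), start=1):
        term = f"SYNT:{i:07d}"
        tm.term_names[term] = f"{cell_type} program"
        for gene in genes:
            tm.mapping.setdefault(gene, set()).add(term)
    return tm
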