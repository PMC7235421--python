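"""The scoring core.

Per cluster and per database, the pipeline is:

1. filter DEGs by log2 fold change and p-value thresholds;
2. build the gene weight vector ``e_j = |LFC_j| * mean(|LFC|)``;
3. build the evidence matrix M and style vector L from the database;
4. raw score per cell type ``s_i = (M e)_i * l_i``;
5. z-score normalize each database's raw score vector (sample std);
6. harmonize all vectors onto the union of candidate cell types
   (missing types filled with 0);
7. weighted sum over databases plus a bias gives the uniform score;
8. rank cell types by uniform score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .formats_io import DEGRecord, DEGTable
from .marker_database import (
    EvidenceMatrix,
    MarkerDatabase,
    StyleVector,
    build_evidence_matrix,
    style_vector,
)

logger = logging.getLogger(__name__)

DEFAULT_LFC_MIN = 1.0
DEFAULT_P_MAX = 0.05
DEFAULT_TOP_N = 5
DEFAULT_AMBIGUITY_RATIO = 2.0
RATIO_SHIFT = 0.001


@dataclass
class GeneWeightVector:
    genes: list[str]
    values: np.ndarray


@dataclass
class ScoreVector:
    """Per-cell-type scores at one pipeline stage."""

    cell_types: list[str]
    values: np.ndarray
    stage: str
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.cell_types, map(float, self.values)))


@dataclass
class WeightSpec:
    """Per-database merge weights w and scalar bias b."""

    weights: Sequence[float]
    bias: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ConfigError("database weights must be non-negative")
        if self.weights and not any(w > 0 for w in self.weights):
            raise ConfigError("at least one database weight must be > 0")


@dataclass
class AnnotationResult:
    cluster: str
    ranking: list[tuple[str, float]] = field(default_factory=list)
    status: str = "unresolved"
    top_n_reported: int = DEFAULT_TOP_N


def filter_degs(
    table: DEGTable,
    cluster: str,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> list[DEGRecord]:
    """Records of one cluster passing LFC >= lfc_min and p <= p_max."""
    if not lfc_min > 0:
        raise ValueError(f"lfc_min must be > 0, got {lfc_min}")
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    return [
        r
        for r in table.records_for(cluster)
        if r.lfc >= lfc_min and r.pvalue <= p_max
    ]


def gene_weight_vector(filtered: list[DEGRecord]) -> GeneWeightVector:
    """e_j = |LFC_j| * mean(|LFC|) over the cluster's filtered DEGs."""
    if not filtered:
        raise ValueError("cannot build a gene weight vector from no records")
    abs_lfc = np.array([abs(r.lfc) for r in filtered])
    return GeneWeightVector(
        [r.gene for r in filtered], abs_lfc * abs_lfc.mean()
    )


def raw_scores(
    matrix: EvidenceMatrix, weights: GeneWeightVector, style: StyleVector
) -> ScoreVector:
    """s_i = (sum_j M[i, j] * e_j) * l_i for each candidate cell type."""
    if matrix.cell_types != style.cell_types:
        raise ValueError("style vector does not align with evidence matrix rows")
    e_by_gene = dict(zip(weights.genes, weights.values))
    try:
        e = np.array([e_by_gene[g] for g in matrix.genes])
    except KeyError as exc:
        raise ValueError(
            f"evidence matrix gene {exc.args[0]!r} missing from weight vector"
        ) from None
    values = (matrix.values @ e) * style.values
    return ScoreVector(list(matrix.cell_types), values, stage="raw")


def zscore_normalize(scores: ScoreVector) -> ScoreVector:
    """Normalize to mean 0, sample standard deviation 1 (divide by p-1).

    A single-element or zero-variance vector cannot be normalized; it is
    returned as all zeros with the ``degenerate`` flag set.
    """
    if scores.stage != "raw":
        raise ValueError(f"expected a raw score vector, got stage {scores.stage!r}")
    v = scores.values.astype(float)
    p = v.size
    if p < 2:
        return ScoreVector(
            list(scores.cell_types), np.zeros(p), "normalized", degenerate=True
        )
    d = float(np.std(v, ddof=1))
    # max == min guards constant vectors whose float mean is inexact
    if d == 0.0 or v.max() == v.min():
        return ScoreVector(
            list(scores.cell_types), np.zeros(p), "normalized", degenerate=True
        )
    return ScoreVector(
        list(scores.cell_types), (v - v.mean()) / d, "normalized"
    )


def harmonize(vectors: list[ScoreVector]) -> list[ScoreVector]:
    """Re-express normalized vectors over the sorted union of cell types.

    Cell types absent from a database's vector are filled with 0, so all
    outputs share one identical ordering.
    """
    non_empty = [v for v in vectors if v.values.size > 0]
    if not non_empty:
        raise ValueError("harmonize needs at least one non-empty score vector")
    union = sorted({ct for v in non_empty for ct in v.cell_types})
    out = []
    for v in vectors:
        lookup = v.as_dict()
        out.append(
            ScoreVector(
                union,
                np.array([lookup.get(ct, 0.0) for ct in union]),
                stage="harmonized",
                degenerate=v.degenerate,
            )
        )
    return out


def combine(harmonized: list[ScoreVector], spec: WeightSpec) -> ScoreVector:
    """Uniform score: weighted sum of harmonized vectors plus the bias."""
    if len(spec.weights) != len(harmonized):
        raise ConfigError(
            f"{len(spec.weights)} weights supplied for "
            f"{len(harmonized)} databases"
        )
    axis = harmonized[0].cell_types
    for v in harmonized[1:]:
        if v.cell_types != axis:
            raise ValueError("harmonized vectors do not share one cell-type axis")
    total = np.full(len(axis), float(spec.bias))
    for w, v in zip(spec.weights, harmonized):
        total = total + w * v.values
    return ScoreVector(
        list(axis),
        total,
        stage="uniform",
        degenerate=any(v.degenerate for v in harmonized),
    )


def rank_annotations(
    uniform: ScoreVector,
    top_n: int = DEFAULT_TOP_N,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
    cluster: str = "",
) -> AnnotationResult:
    """Rank cell types by uniform score, ties broken by name ascending.

    The confidence check compares the top score to the runner-up on a
    shifted-positive scale (minimum score mapped to ``RATIO_SHIFT``), since
    ratios of signed z-scores are meaningless.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if uniform.values.size == 0:
        raise ValueError(
            "empty uniform score vector: route this cluster to the GO fallback"
        )
    order = sorted(
        zip(uniform.cell_types, map(float, uniform.values)),
        key=lambda pair: (-pair[1], pair[0]),
    )
    if len(order) == 1:
        status = "confident"
    else:
        lo = min(score for _, score in order)
        shifted_top = order[0][1] - lo + RATIO_SHIFT
        shifted_second = order[1][1] - lo + RATIO_SHIFT
        status = (
            "confident"
            if shifted_top / shifted_second >= ambiguity_ratio
            else "ambiguous"
        )
    if uniform.degenerate and status == "confident":
        status = "ambiguous"
    return AnnotationResult(
        cluster=cluster,
        ranking=order[:top_n],
        status=status,
        top_n_reported=top_n,
    )


def compute_degs(
    expr: pd.DataFrame,
    labels: Sequence[str],
    epsilon: float = 1.0,
) -> DEGTable:
    """Cluster-vs-rest DEGs by equal-variance two-sided Student's t-test.

    ``expr`` is a genes x cells table; ``labels`` gives each cell's cluster.
    LFC is ``log2((mean_in + eps) / (mean_out + eps))``. All genes are
    reported; thresholding is applied downstream by :func:`filter_degs`.
    """
    labels = [str(lab) for lab in labels]
    if len(labels) != expr.shape[1]:
        raise ValueError(
            f"{len(labels)} labels for {expr.shape[1]} cells"
        )
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValueError("need at least 2 clusters to compute DEGs")
    arr = expr.to_numpy(dtype=float)
    lab_arr = np.array(labels)
    records: list[DEGRecord] = []
    for cluster in unique:
        mask = lab_arr == cluster
        if mask.sum() < 2:
            logger.warning(
                "cluster %r has fewer than 2 cells; skipped", cluster
            )
            continue
        inside, outside = arr[:, mask], arr[:, ~mask]
        tstat, pvals = stats.ttest_ind(inside, outside, axis=1, equal_var=True)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        mean_in = inside.mean(axis=1)
        mean_out = outside.mean(axis=1)
        lfc = np.log2((mean_in + epsilon) / (mean_out + epsilon))
        for gene, l, p, m in zip(expr.index, lfc, pvals, mean_in):
            records.append(
                DEGRecord(
                    gene=str(gene),
                    cluster=cluster,
                    lfc=float(l),
                    pvalue=float(min(max(p, 0.0), 1.0)),
                    mean_expr=float(m),
                )
            )
    return DEGTable.from_records(records, source_dialect="generic")


def score_cluster(
    filtered: list[DEGRecord],
    dbs: Sequence[MarkerDatabase],
    spec: WeightSpec,
) -> ScoreVector | None:
    """Run stages 2-7 for one cluster; None when no database matches.

    Databases with weight 0 contribute nothing to the score and must not
    widen the candidate cell-type union, so they are dropped up front.
    """
    if len(spec.weights) != len(dbs):
        raise ConfigError(
            f"{len(spec.weights)} weights supplied for {len(dbs)} databases"
        )
    kept = [(db, w) for db, w in zip(dbs, spec.weights) if w > 0]
    dbs = [db for db, _ in kept]
    spec = WeightSpec([w for _, w in kept], spec.bias)
    weights_vec = gene_weight_vector(filtered)
    genes = [r.gene for r in filtered]
    zvecs: list[ScoreVector | None] = []
    for db in dbs:
        matrix = build_evidence_matrix(db, genes)
        if matrix.is_empty:
            zvecs.append(None)
            continue
        style = style_vector(matrix)
        raw = raw_scores(matrix, weights_vec, style)
        zvecs.append(zscore_normalize(raw))
    present = [z for z in zvecs if z is not None]
    if not present:
        return None
    harmonized_present = iter(harmonize(present))
    axis = None
    full: list[ScoreVector] = []
    for z in zvecs:
        if z is not None:
            h = next(harmonized_present)
            axis = h.cell_types
            full.append(h)
        else:
            full.append(None)  # placeholder, filled below
    zero = ScoreVector(list(axis), np.zeros(len(axis)), stage="harmonized")
    full = [h if h is not None else zero for h in full]
    return combine(full, spec)


def annotate(
    table: DEGTable,
    dbs: Sequence[MarkerDatabase],
    spec: WeightSpec | None = None,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    top_n: int = DEFAULT_TOP_N,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
) -> list[AnnotationResult]:
    """Annotate every cluster in the table against the databases.

    Clusters with no marker evidence in any database come back with status
    ``unresolved`` and an empty ranking; the caller may route them to the
    GO-enrichment fallback. Results are ordered by cluster label.
    """
    if not dbs:
        raise ConfigError("at least one marker database is required")
    if spec is None:
        spec = WeightSpec(weights=[db.weight for db in dbs])
    results = []
    for cluster in sorted(table.clusters()):
        filtered = filter_degs(table, cluster, lfc_min=lfc_min, p_max=p_max)
        if not filtered:
            results.append(AnnotationResult(cluster=cluster))
            continue
        uniform = score_cluster(filtered, dbs, spec)
        if uniform is None:
            results.append(AnnotationResult(cluster=cluster))
            continue
        results.append(
            rank_annotations(
                uniform,
                top_n=top_n,
                ambiguity_ratio=ambiguity_ratio,
                cluster=cluster,
            )
        )
    return results
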