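"""Fallback functional characterization for clusters without marker hits.

Foreground = DEGs of the query cluster, background = DEGs of the other
clusters (made disjoint from the foreground). Each term is tested with a
one-sided Fisher's exact test (enrichment direction) and p-values are
adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .formats_io import TermMap, normalize_gene


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: foreground/background x in-term/not-in-term."""

    a: int  # foreground genes in the term
    b: int  # foreground genes not in the term
    c: int  # background genes in the term
    d: int  # background genes not in the term

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative contingency cell in {self}")


@dataclass
class EnrichmentResult:
    term: str
    table: ContingencyTable
    pvalue: float
    qvalue: float
    fold: float
    term_name: str | None = None


def build_tables(
    fg: Iterable[str], bg: Iterable[str], terms: TermMap
) -> dict[str, ContingencyTable]:
    """One contingency table per term with at least one foreground gene.

    Genes present in both sets are dropped from the background; the testing
    universe is restricted to genes annotated in the term map.
    """
    fg_set = {normalize_gene(g) for g in fg}
    bg_set = {normalize_gene(g) for g in bg} - fg_set
    universe = terms.genes()
    fg_u = fg_set & universe
    if not fg_u:
        raise ValueError(
            "no foreground gene is annotated in the term map; nothing to test"
        )
    bg_u = bg_set & universe
    tables = {}
    for term, term_genes in terms.terms_to_genes().items():
        a = len(fg_u & term_genes)
        if a == 0:
            continue
        c = len(bg_u & term_genes)
        tables[term] = ContingencyTable(a, len(fg_u) - a, c, len(bg_u) - c)
    return tables


def _upper_tail(a, n_total, in_term, fg_total):
    # P(X >= a), X ~ Hypergeom(N=n_total, K=in_term, n=fg_total)
    return stats.hypergeom.sf(a - 1, n_total, in_term, fg_total)


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided enrichment p-value: P(X >= a) for the hypergeometric X."""
    n_total = table.a + table.b + table.c + table.d
    return float(
        _upper_tail(table.a, n_total, table.a + table.c, table.a + table.b)
    )


def fisher_exact_greater_batch(a, b, c, d) -> np.ndarray:
    """Vectorized :func:`fisher_exact_greater` over parallel count arrays."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(np.stack([a, b, c, d]) < 0):
        raise ValueError("negative contingency cell")
    return np.asarray(_upper_tail(a, a + b + c + d, a + c, a + b), dtype=float)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, original input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return [float(q) for q in out]


def _fold_change(t: ContingencyTable) -> float:
    fg_rate = t.a / (t.a + t.b) if (t.a + t.b) else math.nan
    bg_rate = t.c / (t.c + t.d) if (t.c + t.d) else math.nan
    if math.isnan(fg_rate) or math.isnan(bg_rate):
        return math.nan
    if bg_rate == 0:
        return math.inf
    return fg_rate / bg_rate


def enrich(
    fg: Iterable[str],
    bg: Iterable[str],
    terms: TermMap,
    q_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Enriched terms at BH-adjusted q <= q_max, sorted by (q, term)."""
    tables = build_tables(fg, bg, terms)
    term_ids = sorted(tables)
    pvals = [fisher_exact_greater(tables[t]) for t in term_ids]
    qvals = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term=t,
            table=tables[t],
            pvalue=p,
            qvalue=q,
            fold=_fold_change(tables[t]),
            term_name=terms.term_names.get(t),
        )
        for t, p, q in zip(term_ids, pvals, qvals)
        if q <= q_max
    ]
    results.sort(key=lambda r: (r.qvalue, r.term))
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as a TSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["term", "term_name", "fg_in", "fg_total", "bg_in", "bg_total",
             "fold", "pvalue", "qvalue"]
        )
        for r in results:
            t = r.table
            writer.writerow(
                [r.term, r.term_name or "", t.a, t.a + t.b, t.c, t.c + t.d,
                 f"{r.fold:.6g}", f"{r.pvalue:.6g}", f"{r.qvalue:.6g}"]
            )
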