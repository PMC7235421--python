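# cellanno

Automatic cell-type annotation for clustered scRNA-seq data. Given
per-cluster differential-expression tables (CellRanger or Seurat output)
and one or more marker-gene databases, `cellanno` scores every candidate
cell type per cluster by combining the strength of differential expression
with the amount of literature evidence behind each marker, and reports a
ranked annotation. Clusters matching no known marker can fall back to a
term-enrichment analysis (one-sided Fisher's exact test with
Benjamini-Hochberg correction) to hint at their function.

## How scoring works

For each cluster and each database:

1. DEGs are filtered by log2 fold change and p-value (defaults
   `LFC >= 1`, `P <= 0.05`).
2. A gene weight vector is built: `e_j = |LFC_j| * mean(|LFC|)`.
3. Genes shared between the cluster's DEGs and the database form a
   cell-type x gene evidence matrix `M`, with entries `log2(a) + 0.05`
   where `a` is the number of supporting references.
4. A style vector `L` per cell type multiplies the population standard
   deviation of its matched evidence by the number of matched markers
   (single-marker rows use a std factor of 1).
5. Raw scores `S = (M e) * L` are z-score normalized (sample std),
   zero-filled over the union of candidate cell types across databases,
   weighted per database and summed (plus an optional bias) into one
   uniform score per cell type, which drives the ranking.

## CLI

```bash
# annotate clusters from a Seurat FindAllMarkers CSV against a
# user marker database (cell type <tab> gene; repeat a pair to raise
# its evidence count) and the small packaged reference table:
cellanno annotate \
    --input markers.csv --dialect seurat \
    --db my_markers.tsv:1.0 --db builtin --species human \
    --lfc-min 1 --p-max 0.05 --top-n 5 \
    --term-map go_map.tsv --out results/

# enrichment of one cluster's DEGs vs the other clusters' DEGs:
cellanno enrich --input markers.csv --dialect seurat --cluster 3 \
    --term-map go_map.tsv --out cluster3_enrichment.tsv

# synthetic fixtures with planted ground truth, in every supported dialect:
cellanno fixtures --spec fixture_spec.json --seed 7 --out fixtures/
```

`--db` accepts `path[:weight]` and may be repeated; `builtin` selects the
packaged reference table (`src/cellanno/data/reference_markers.tsv`, a
small table in the schema `species / tissue / cell_type / gene_symbol /
ref_count`). Full CellMarker/CancerSEA dumps can be dropped in as TSVs in
the same schema; give functional-state databases a reduced weight (e.g.
`cancersea.tsv:0.5`) so they stay visible but sub-dominant. Logs go to
stderr; all results are files.

Annotation output (`annotation.tsv`) columns: `cluster`, `rank`,
`cell_type`, `uniform_score`, `status` where status is `confident`,
`ambiguous` (top score less than twice the runner-up on a shifted-positive
scale, or a degenerate score vector) or `unresolved` (no marker evidence in
any database; triggers the enrichment fallback when a term map is
supplied).

## Python API

```python
import cellanno

table = cellanno.read_seurat_markers("markers.csv")
db = cellanno.read_user_marker_db("my_markers.tsv")
results = cellanno.annotate(table, [db])
cellanno.write_annotation(results, "annotation.tsv")
```

DEGs can also be computed from a raw expression matrix with
`cellanno.compute_degs(expr, labels)` (cluster-vs-rest pooled-variance
Student's t-test; `LFC = log2((mean_in + 1) / (mean_out + 1))`), then
filtered with `P < 0.001`, `LFC >= 1`.

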