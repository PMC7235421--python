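import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellanno.annotation_model import (
    ScoreVector,
    WeightSpec,
    annotate,
    combine,
    compute_degs,
    filter_degs,
    gene_weight_vector,
    harmonize,
    rank_annotations,
    raw_scores,
    score_cluster,
    zscore_normalize,
)
from cellanno.errors import ConfigError
from cellanno.formats_io import DEGRecord, DEGTable
from cellanno.marker_database import (
    MarkerDatabase,
    build_evidence_matrix,
    style_vector,
)


def make_table(rows):
    return DEGTable.from_records(
        [DEGRecord(g, c, lfc, p) for g, c, lfc, p in rows]
    )


class TestFilterDegs:
    def test_threshold_scan(self):
        rows = [("G1", "0", 1.2, 0.01), ("G2", "0", 0.5, 0.01), ("G3", "0", 2.0, 0.2)]
        table = make_table(rows)
        out = filter_degs(table, "0", 1.0, 0.05)
        # brute-force scan
        expected = [g for g, c, l, p in rows if l >= 1.0 and p <= 0.05]
        assert [r.gene for r in out] == expected == ["G1"]

    def test_pbmc_profile(self):
        rows = [("G1", "0", 1.2, 0.01), ("G2", "0", 1.6, 0.01), ("G3", "0", 2.0, 0.2)]
        out = filter_degs(make_table(rows), "0", lfc_min=1.5, p_max=0.05)
        assert [r.gene for r in out] == ["G2"]

    def test_nonpositive_lfc_min_rejected(self):
        with pytest.raises(ValueError):
            filter_degs(make_table([("G1", "0", 1.0, 0.01)]), "0", lfc_min=0.0)

    def test_all_pass_is_identity(self):
        rows = [("G1", "0", 2.0, 0.01), ("G2", "0", 3.0, 0.02)]
        table = make_table(rows)
        assert filter_degs(table, "0") == table.records_for("0")

    def test_unknown_cluster(self):
        with pytest.raises(KeyError):
            filter_degs(make_table([("G1", "0", 2.0, 0.01)]), "7")


class TestGeneWeightVector:
    def test_mean_scaling(self):
        recs = [DEGRecord(f"G{i}", "0", l, 0.01) for i, l in enumerate([1, 2, 3])]
        gw = gene_weight_vector(recs)
        assert gw.values == pytest.approx([2.0, 4.0, 6.0])

    def test_single_record_squares(self):
        gw = gene_weight_vector([DEGRecord("G1", "0", 1.7, 0.01)])
        assert gw.values == pytest.approx([1.7**2])

    def test_equal_lfcs(self):
        recs = [DEGRecord(f"G{i}", "0", 2.5, 0.01) for i in range(4)]
        assert gene_weight_vector(recs).values == pytest.approx([6.25] * 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_weight_vector([])


class TestRawScores:
    def _setup(self, counts, genes, lfcs):
        db = MarkerDatabase("user", counts)
        recs = [DEGRecord(g, "0", l, 0.01) for g, l in zip(genes, lfcs)]
        m = build_evidence_matrix(db, [r.gene for r in recs])
        return m, gene_weight_vector(recs), style_vector(m)

    def test_single_cell_product(self):
        m, gw, sv = self._setup({("T", "G1"): 1}, ["G1"], [math.sqrt(2.0)])
        s = raw_scores(m, gw, sv)
        # M=[[0.05]], e=[2], l=[1] -> 0.1
        assert s.values == pytest.approx([0.1])

    def test_zero_style_annihilates(self):
        m, gw, _ = self._setup(
            {("T", "G1"): 3, ("T", "G2"): 3}, ["G1", "G2"], [1.0, 2.0]
        )
        sv = style_vector(m)
        assert sv.values == pytest.approx([0.0])
        assert raw_scores(m, gw, sv).values == pytest.approx([0.0])

    def test_linear_in_gene_weights(self):
        m, gw, sv = self._setup(
            {("T", "G1"): 2, ("T", "G2"): 8, ("B", "G2"): 3},
            ["G1", "G2"],
            [1.2, 2.4],
        )
        s1 = raw_scores(m, gw, sv).values
        gw.values = gw.values * 2
        s2 = raw_scores(m, gw, sv).values
        assert s2 == pytest.approx(2 * s1)

    def test_misaligned_gene_errors(self):
        m, gw, sv = self._setup({("T", "G1"): 2}, ["G1"], [1.0])
        gw.genes = ["OTHER"]
        with pytest.raises(ValueError):
            raw_scores(m, gw, sv)


class TestZscore:
    def test_one_two_three(self):
        s = ScoreVector(["A", "B", "C"], np.array([1.0, 2.0, 3.0]), "raw")
        z = zscore_normalize(s)
        assert z.values == pytest.approx([-1.0, 0.0, 1.0])
        assert not z.degenerate

    def test_zero_variance_degenerate(self):
        s = ScoreVector(["A", "B"], np.array([4.0, 4.0]), "raw")
        z = zscore_normalize(s)
        assert z.values == pytest.approx([0.0, 0.0])
        assert z.degenerate

    def test_singleton_degenerate(self):
        z = zscore_normalize(ScoreVector(["A"], np.array([7.0]), "raw"))
        assert z.values == pytest.approx([0.0])
        assert z.degenerate

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_identity(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 10, rng.integers(2, 12))
        if np.std(v, ddof=1) == 0:
            pytest.skip("degenerate draw")
        z = zscore_normalize(
            ScoreVector([f"C{i}" for i in range(v.size)], v, "raw")
        )
        assert abs(z.values.mean()) < 1e-9
        assert abs(np.std(z.values, ddof=1) - 1) < 1e-9


class TestHarmonize:
    def test_disjoint_union_zero_fill(self):
        v1 = ScoreVector(["A"], np.array([1.0]), "normalized")
        v2 = ScoreVector(["B"], np.array([-0.5]), "normalized")
        h1, h2 = harmonize([v1, v2])
        assert h1.cell_types == h2.cell_types == ["A", "B"]
        assert h1.values == pytest.approx([1.0, 0.0])
        assert h2.values == pytest.approx([0.0, -0.5])

    def test_identical_sets_canonical_order(self):
        v1 = ScoreVector(["B", "A"], np.array([2.0, 1.0]), "normalized")
        (h1,) = harmonize([v1])
        assert h1.cell_types == ["A", "B"]
        assert h1.values == pytest.approx([1.0, 2.0])

    def test_union_size(self):
        rng = np.random.default_rng(0)
        sets = [
            [f"C{i}" for i in rng.choice(10, size=rng.integers(1, 6), replace=False)]
            for _ in range(3)
        ]
        vectors = [
            ScoreVector(list(s), np.arange(len(s), dtype=float), "normalized")
            for s in sets
        ]
        out = harmonize(vectors)
        expected = set().union(*map(set, sets))
        assert all(len(h.cell_types) == len(expected) for h in out)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            harmonize([ScoreVector([], np.array([]), "normalized")])


class TestCombine:
    def test_identity_merge(self):
        v = ScoreVector(["A", "B"], np.array([0.3, -0.3]), "harmonized")
        out = combine([v], WeightSpec([1.0]))
        assert out.values == pytest.approx(v.values)

    def test_zero_weight_ignores_database(self):
        v1 = ScoreVector(["A", "B"], np.array([1.0, 0.0]), "harmonized")
        v2 = ScoreVector(["A", "B"], np.array([9.0, 9.0]), "harmonized")
        out = combine([v1, v2], WeightSpec([1.0, 0.0]))
        assert out.values == pytest.approx(v1.values)

    def test_elementwise_weighted_sum(self):
        v1 = ScoreVector(["A", "B"], np.array([1.0, 0.0]), "harmonized")
        v2 = ScoreVector(["A", "B"], np.array([0.0, 2.0]), "harmonized")
        out = combine([v1, v2], WeightSpec([1.0, 1.0], bias=0.0))
        assert out.values == pytest.approx([1.0, 2.0])

    def test_bias_added(self):
        v = ScoreVector(["A"], np.array([1.0]), "harmonized")
        assert combine([v], WeightSpec([2.0], bias=0.5)).values == pytest.approx([2.5])

    def test_weight_length_mismatch(self):
        v = ScoreVector(["A"], np.array([1.0]), "harmonized")
        with pytest.raises(ConfigError):
            combine([v], WeightSpec([1.0, 1.0]))


class TestRankAnnotations:
    def test_ratio_rule_confident(self):
        u = ScoreVector(["A", "B"], np.array([3.0, 1.0]), "uniform")
        res = rank_annotations(u, ambiguity_ratio=2.0)
        assert [ct for ct, _ in res.ranking] == ["A", "B"]
        assert res.status == "confident"

    def test_tie_breaks_lexicographically_and_is_ambiguous(self):
        u = ScoreVector(["B", "A"], np.array([2.0, 2.0]), "uniform")
        res = rank_annotations(u)
        assert [ct for ct, _ in res.ranking] == ["A", "B"]
        assert res.status == "ambiguous"

    def test_truncation(self):
        u = ScoreVector(["A", "B", "C"], np.array([3.0, 2.0, 1.0]), "uniform")
        assert len(rank_annotations(u, top_n=5).ranking) == 3

    def test_single_candidate_confident_unless_degenerate(self):
        u = ScoreVector(["A"], np.array([1.0]), "uniform")
        assert rank_annotations(u).status == "confident"
        u_deg = ScoreVector(["A"], np.array([0.0]), "uniform", degenerate=True)
        assert rank_annotations(u_deg).status == "ambiguous"

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            rank_annotations(ScoreVector([], np.array([]), "uniform"))


class TestComputeDegs:
    def test_exclusive_gene_lfc(self):
        # in-mean 8, out-mean 0, eps 1 -> LFC = log2(9)
        expr = pd.DataFrame(
            [[8.0, 8.0, 8.0, 0.0, 0.0, 0.0], [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]],
            index=["MK", "HK"],
            columns=[f"c{i}" for i in range(6)],
        )
        table = compute_degs(expr, ["A", "A", "A", "B", "B", "B"])
        rec = next(r for r in table.records if r.gene == "MK" and r.cluster == "A")
        assert rec.lfc == pytest.approx(math.log2(9.0), abs=1e-12)

    def test_null_gene_flat(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5, 1, 40)
        expr = pd.DataFrame([np.concatenate([v[:20], v[:20]])],
                            index=["G"], columns=[f"c{i}" for i in range(40)])
        table = compute_degs(expr, ["A"] * 20 + ["B"] * 20)
        rec = table.records[0]
        assert rec.pvalue == pytest.approx(1.0)
        assert rec.lfc == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_pooled_t(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        expr = pd.DataFrame([x + y], index=["G"],
                            columns=[f"c{i}" for i in range(6)])
        table = compute_degs(expr, ["A"] * 3 + ["B"] * 3)
        rec = next(r for r in table.records if r.cluster == "A")
        # hand-computed pooled-variance t: means 2 and 4, s^2 = 1 and 4
        sp2 = (2 * 1.0 + 2 * 4.0) / 4
        t = (2.0 - 4.0) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected_p = 2 * stats.t.sf(abs(t), df=4)
        assert rec.pvalue == pytest.approx(expected_p, abs=1e-12)

    def test_tiny_cluster_skipped(self, caplog):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["G"],
                            columns=list("abcde"))
        with caplog.at_level("WARNING"):
            table = compute_degs(expr, ["A", "A", "B", "B", "C"])
        assert set(table.clusters()) == {"A", "B"}

    def test_single_cluster_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=["a", "b"])
        with pytest.raises(ValueError):
            compute_degs(expr, ["A", "A"])


class TestAnnotate:
    def _db(self):
        return MarkerDatabase(
            "user",
            {
                ("T cell", "CD3E"): 2, ("T cell", "CD3D"): 5,
                ("B cell", "CD19"): 3, ("B cell", "MS4A1"): 6,
            },
        )

    def test_planted_truth(self):
        table = make_table(
            [
                ("CD3E", "1", 2.0, 0.001), ("CD3D", "1", 3.0, 0.001),
                ("CD19", "2", 2.5, 0.001), ("MS4A1", "2", 2.2, 0.001),
            ]
        )
        results = annotate(table, [self._db()])
        by_cluster = {r.cluster: r for r in results}
        assert by_cluster["1"].ranking[0][0] == "T cell"
        assert by_cluster["2"].ranking[0][0] == "B cell"

    def test_no_match_is_unresolved(self):
        table = make_table([("FOO", "1", 2.0, 0.001)])
        (res,) = annotate(table, [self._db()])
        assert res.status == "unresolved"
        assert res.ranking == []

    def test_zero_weight_second_db_changes_nothing(self):
        table = make_table(
            [("CD3E", "1", 2.0, 0.001), ("CD19", "1", 1.5, 0.001)]
        )
        decoy = MarkerDatabase("decoy", {("Weird cell", "CD3E"): 9})
        base = annotate(table, [self._db()])
        spec = WeightSpec([1.0, 0.0])
        with_decoy = annotate(table, [self._db(), decoy], spec)
        assert [r.ranking for r in base] == [r.ranking for r in with_decoy]


class TestPipelineProperties:
    @staticmethod
    def _random_instance(rng):
        n_types = rng.integers(2, 6)
        n_genes = rng.integers(2, 9)
        genes = [f"G{j}" for j in range(n_genes)]
        lfcs = rng.uniform(1.0, 4.0, n_genes)
        n_dbs = rng.integers(1, 3)
        dbs = []
        for _ in range(n_dbs):
            entries = {}
            for i in range(n_types):
                for g in genes:
                    if rng.random() < 0.4:
                        entries[(f"T{i}", g)] = int(rng.integers(1, 11))
            if entries:
                dbs.append(MarkerDatabase("r", entries))
        weights = list(rng.uniform(0.2, 2.0, len(dbs)))
        bias = float(rng.normal())
        return genes, lfcs, dbs, weights, bias

    def test_scale_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            genes, lfcs, dbs, weights, bias = self._random_instance(rng)
            if not dbs:
                continue
            recs = [DEGRecord(g, "0", l, 0.001) for g, l in zip(genes, lfcs)]
            scaled = [
                DEGRecord(g, "0", l * 3.7, 0.001) for g, l in zip(genes, lfcs)
            ]
            spec = WeightSpec(weights, bias)
            u1 = score_cluster(recs, dbs, spec)
            u2 = score_cluster(scaled, dbs, spec)
            if u1 is None:
                assert u2 is None
                continue
            r1 = rank_annotations(u1).ranking
            r2 = rank_annotations(u2).ranking
            assert [ct for ct, _ in r1] == [ct for ct, _ in r2]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            genes, lfcs, dbs, weights, bias = self._random_instance(rng)
            if not dbs:
                continue
            recs = [DEGRecord(g, "0", l, 0.001) for g, l in zip(genes, lfcs)]
            spec = WeightSpec(weights, bias)
            u1 = score_cluster(recs, dbs, spec)
            # permute genes, db entry order, and database order (+weights)
            perm = rng.permutation(len(recs))
            recs_p = [recs[i] for i in perm]
            db_perm = rng.permutation(len(dbs))
            dbs_p = [
                MarkerDatabase(
                    "r",
                    dict(
                        sorted(
                            dbs[i].entries.items(),
                            key=lambda kv: hash(kv[0]),
                        )
                    ),
                )
                for i in db_perm
            ]
            spec_p = WeightSpec([weights[i] for i in db_perm], bias)
            u2 = score_cluster(recs_p, dbs_p, spec_p)
            if u1 is None:
                assert u2 is None
                continue
            assert u1.cell_types == u2.cell_types
            assert u1.values == pytest.approx(u2.values, abs=1e-9)

    def test_monotonicity_in_single_marker_lfc(self):
        db = MarkerDatabase(
            "user",
            {("T", "G1"): 2, ("T", "G2"): 7, ("B", "G3"): 4, ("B", "G1"): 3},
        )
        base_lfcs = {"G1": 1.5, "G2": 2.0, "G3": 2.5}

        def raw_score_of_T(g2_lfc):
            recs = [
                DEGRecord(g, "0", g2_lfc if g == "G2" else l, 0.001)
                for g, l in base_lfcs.items()
            ]
            m = build_evidence_matrix(db, [r.gene for r in recs])
            s = raw_scores(m, gene_weight_vector(recs), style_vector(m))
            return s.as_dict()["T"]

        scores = [raw_score_of_T(x) for x in np.linspace(1.0, 6.0, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))
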