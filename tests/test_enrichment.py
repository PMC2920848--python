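import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwasea.enrichment import (
    GeneSet,
    bonferroni_adjust,
    enrichment_cutoff,
    leading_edge_test,
    prune_clustered_genes,
    ranksum_test,
    read_gmt,
    run_enrichment,
    write_gmt,
)

from conftest import make_scores


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [
            GeneSet("S1", "first", ("A", "B", "C")),
            GeneSet("S2", "second", ("B", "D")),
        ]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc-only\n")
        with pytest.raises(ValueError):
            read_gmt(path)

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("S", "d", ())


class TestPruning:
    def test_shared_best_snp_keeps_most_significant(self):
        scores = make_scores([0.01, 0.20, 0.5], best_snp=["rs1", "rs1", "rs2"])
        retained, n_pruned = prune_clustered_genes(["G0000", "G0001", "G0002"], scores)
        assert retained == ["G0000", "G0002"]
        assert n_pruned == 1

    def test_distinct_best_snps_untouched(self):
        scores = make_scores([0.1, 0.2, 0.3])
        retained, n_pruned = prune_clustered_genes(["G0000", "G0001", "G0002"], scores)
        assert n_pruned == 0 and len(retained) == 3

    def test_three_gene_cluster_prunes_two(self):
        scores = make_scores([0.3, 0.1, 0.2], best_snp=["rs9", "rs9", "rs9"])
        retained, n_pruned = prune_clustered_genes(["G0000", "G0001", "G0002"], scores)
        assert retained == ["G0001"] and n_pruned == 2

    def test_tie_broken_by_smallest_symbol(self):
        scores = make_scores([0.1, 0.1], best_snp=["rs1", "rs1"])
        retained, _ = prune_clustered_genes(["G0001", "G0000"], scores)
        assert retained == ["G0000"]


class TestLeadingEdge:
    def test_fraction_counting(self):
        # 100 genes, 5 clearly separated significant ones genome-wide; the
        # set's 3 significant members out of 10 give a leading-edge fraction 0.3
        p = np.concatenate([np.linspace(0.001, 0.005, 5), np.linspace(0.2, 0.99, 95)])
        scores = make_scores(p)
        # 3 of the 5 genome-wide significant genes plus 7 insignificant ones
        members = [f"G{i:04d}" for i in [0, 1, 2, 10, 11, 12, 13, 14, 15, 16]]
        res = leading_edge_test(members, scores, seed=1)
        assert res.leading_edge_fraction == pytest.approx(0.3)
        assert res.n_effective == 10

    def test_matches_exact_hypergeometric(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n, size = 100, 5
            scores = make_scores(rng.uniform(size=n))
            members = [f"G{i:04d}" for i in rng.choice(n, size=size, replace=False)]
            exact = leading_edge_test(members, scores, seed=trial, null_method="hypergeom")
            sampled = leading_edge_test(
                members, scores, seed=trial, null_method="sampled",
                n_null=4000, adaptive=False,
            )
            se = np.sqrt(max(exact.p_nominal * (1 - exact.p_nominal), 1e-6) / 4000)
            assert sampled.p_nominal == pytest.approx(exact.p_nominal, abs=max(3 * se, 1.5 / 4000))
            assert exact.null_method == "hypergeom"

    def test_hypergeometric_example_two_of_five(self):
        # genome of 100 genes, 5 above cutoff; a set of 5 holding 2 of them:
        # P(X >= 2), X ~ Hypergeom(N=100, K=5, n=5) = 0.001938...
        p = np.concatenate([np.linspace(1e-4, 0.04, 5), np.linspace(0.06, 0.99, 95)])
        scores = make_scores(p)
        members = ["G0000", "G0001", "G0010", "G0011", "G0012"]
        res = leading_edge_test(members, scores, seed=0)
        expected = stats.hypergeom.sf(1, 100, 5, 5)
        assert res.p_nominal == pytest.approx(expected, rel=1e-9)

    def test_zero_fraction_gives_p_one(self):
        p = np.concatenate([np.linspace(1e-4, 0.04, 5), np.linspace(0.06, 0.99, 95)])
        scores = make_scores(p)
        members = [f"G{i:04d}" for i in range(50, 60)]
        res = leading_edge_test(members, scores, seed=0)
        assert res.leading_edge_fraction == 0.0
        assert res.p_nominal == pytest.approx(1.0)

    def test_unknown_members_counted_not_fatal(self):
        scores = make_scores(np.linspace(0.01, 0.99, 50))
        res = leading_edge_test(["G0001", "NOT_A_GENE"], scores, seed=0, min_set_size=1)
        assert res.n_no_snps == 1
        assert res.n_effective == 1

    def test_no_scored_members_warns_p_one(self, caplog):
        scores = make_scores(np.linspace(0.01, 0.99, 50))
        with caplog.at_level("WARNING"):
            res = leading_edge_test(["NOPE1", "NOPE2"], scores, seed=0)
        assert res.p_nominal == 1.0 and res.n_effective == 0

    def test_below_min_size_flagged(self):
        scores = make_scores(np.linspace(0.01, 0.99, 50))
        res = leading_edge_test(["G0001", "G0002"], scores, seed=0)
        assert res.below_min_size

    def test_determinism_and_substream_stability(self):
        rng = np.random.default_rng(7)
        scores = make_scores(
            rng.uniform(size=200),
            best_snp=[f"rs{i // 2}" for i in range(200)],  # clusters force sampling
        )
        members = [f"G{i:04d}" for i in range(0, 40, 2)]
        a = leading_edge_test(members, scores, seed=3, set_id="X", n_null=500, adaptive=False)
        b = leading_edge_test(members, scores, seed=3, set_id="X", n_null=500, adaptive=False)
        assert a == b
        assert a.null_method == "sampled"

    def test_cluster_pruning_applied_to_observed_and_null(self):
        # 100 genes in 50 best-SNP pairs: effective sizes halve on both sides
        rng = np.random.default_rng(11)
        scores = make_scores(rng.uniform(size=100), best_snp=[f"rs{i // 2}" for i in range(100)])
        members = [f"G{i:04d}" for i in range(20)]  # 10 clusters
        res = leading_edge_test(members, scores, seed=5, n_null=500, adaptive=False)
        assert res.n_pruned_clustering == 10
        assert res.n_effective == 10

    def test_sampling_null_is_valid_p_value(self):
        """Super-uniformity of the nominal p under the null: P(p <= t) <= t
        (the discrete leading-edge statistic makes the test conservative,
        never anti-conservative)."""
        rng = np.random.default_rng(23)
        n_rep = 400
        pvals = np.empty(n_rep)
        scores = make_scores(rng.uniform(size=300))
        for i in range(n_rep):
            members = [f"G{j:04d}" for j in rng.choice(300, size=25, replace=False)]
            pvals[i] = leading_edge_test(members, scores, seed=i).p_nominal
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            emp = (pvals <= t).mean()
            assert emp <= t + 3 * np.sqrt(t * (1 - t) / n_rep)


class TestRankSum:
    def test_top_ranked_members_are_extreme(self):
        scores = make_scores(np.linspace(1e-5, 0.99, 200))
        members = [f"G{i:04d}" for i in range(15)]  # the 15 most significant genes
        res = ranksum_test(members, scores, seed=0, n_null=2000, adaptive=False)
        assert res.p_nominal <= 1 / 1000

    def test_identical_score_multisets_identical_statistic(self):
        vals = np.linspace(0.01, 0.99, 400)
        scores = make_scores(vals)
        # two disjoint sets picking identical score values
        a = [f"G{i:04d}" for i in range(0, 20, 2)]
        b = [f"G{i:04d}" for i in range(1, 21, 2)]
        scores.loc[b, "p_corrected"] = scores.loc[a, "p_corrected"].to_numpy()
        ra = ranksum_test(a, scores, seed=9, set_id="same", n_null=500, adaptive=False)
        rb = ranksum_test(b, scores, seed=9, set_id="same", n_null=500, adaptive=False)
        assert ra.p_nominal == rb.p_nominal

    def test_observed_statistic_matches_scipy(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        scores = make_scores(p)
        members = [f"G{i:04d}" for i in rng.choice(500, size=30, replace=False)]
        pos = scores.index.get_indexer(members)
        expected = stats.mannwhitneyu(
            p[pos], np.delete(p, pos), alternative="less",
            method="asymptotic", use_continuity=False,
        ).pvalue
        from gwasea.enrichment import _match_members, _ranksum_p_from_ranksum

        present, _, scored = _match_members(
            GeneSet("t", "", tuple(members)), scores
        )
        ranks = stats.rankdata(scored["p_corrected"].to_numpy())
        n_total = len(scored)
        obs = _ranksum_p_from_ranksum(
            np.array([ranks[scored.index.get_indexer(present)].sum()]),
            np.array([len(present)]), n_total, 0.0,
        )[0]
        assert obs == pytest.approx(expected, rel=1e-9)

    def test_random_members_give_unremarkable_p(self):
        rng = np.random.default_rng(5)
        scores = make_scores(rng.uniform(size=300))
        reps = [
            ranksum_test(
                [f"G{i:04d}" for i in rng.choice(300, 20, replace=False)],
                scores, seed=j, n_null=300, adaptive=False,
            ).p_nominal
            for j in range(40)
        ]
        # calibrated: roughly uniform, so the mean sits near 0.5
        assert 0.25 < float(np.mean(reps)) < 0.75


class TestBonferroni:
    def test_examples(self):
        scores = make_scores(np.linspace(0.01, 0.99, 60))

        def res(p):
            r = leading_edge_test([f"G{i:04d}" for i in range(10)], scores, seed=0)
            r.p_nominal = p
            return r

        (one,) = bonferroni_adjust([res(0.01)])
        assert one.p_bonferroni == pytest.approx(0.01)
        five = bonferroni_adjust([res(0.01) for _ in range(5)])
        assert all(r.p_bonferroni == pytest.approx(0.05) for r in five)
        ten = bonferroni_adjust([res(0.5) for _ in range(10)])
        assert all(r.p_bonferroni == 1.0 for r in ten)

    def test_run_enrichment_batch(self):
        rng = np.random.default_rng(2)
        scores = make_scores(rng.uniform(size=200))
        sets = [
            GeneSet(f"S{k}", "", tuple(f"G{i:04d}" for i in rng.choice(200, 15, replace=False)))
            for k in range(4)
        ]
        results = run_enrichment(sets, scores, seed=0)
        assert len(results) == 4
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_nominal * 4))


def test_cutoff_is_genomewide_significance_percentile():
    scores = make_scores(np.linspace(0.005, 1.0, 200))
    cut = enrichment_cutoff(scores, 95.0)
    # ~5% of genes should beat the cutoff
    frac = (scores["p_corrected"] < cut).mean()
    assert frac == pytest.approx(0.05, abs=0.01)
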