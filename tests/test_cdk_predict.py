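"""Empirical CDK prediction logic, bootstrap frequency comparison,
Cy-motif scanning, KS distances, and hypergeometric ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosdyn.cdk_predict import (compare_cluster_frequencies,
                                 compare_distance_distributions,
                                 cy_distance_table, find_cy_motifs,
                                 ora_hypergeometric, predict_empirical_cdk)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _inputs(rows):
    """rows: dict site -> (prob, cluster, fdr, log_fc)."""
    probs = pd.DataFrame({"CDK1": {s: v[0] for s, v in rows.items()}})
    clusters = pd.Series({s: v[1] for s, v in rows.items()})
    diff = pd.DataFrame({
        "feature_id": list(rows), "time_min": 90,
        "log_fc": [v[3] for v in rows.values()],
        "fdr": [v[2] for v in rows.values()]})
    return probs, clusters, diff


DYN = {"fast": "c_fast", "slow": "c_slow"}


class TestPredictEmpirical:
    def test_all_filters_pass(self):
        probs, clusters, diff = _inputs({"s1": (0.9, "c_fast", 0.01, 1.0)})
        out = predict_empirical_cdk(probs, {"CDK1": 0.5}, clusters, DYN,
                                    diff, cdk_kinases=("CDK1",))
        assert out.loc["s1", "empirical"] and out.loc["s1", "theoretical"]

    def test_not_significant_blocks_empirical_only(self):
        probs, clusters, diff = _inputs({"s1": (0.9, "c_fast", 0.2, 1.0)})
        out = predict_empirical_cdk(probs, {"CDK1": 0.5}, clusters, DYN,
                                    diff, cdk_kinases=("CDK1",))
        assert out.loc["s1", "theoretical"] and not out.loc["s1", "empirical"]

    def test_wrong_cluster_blocks_empirical(self):
        probs, clusters, diff = _inputs({"s1": (0.9, "c_other", 0.01, 1.0)})
        out = predict_empirical_cdk(probs, {"CDK1": 0.5}, clusters, DYN,
                                    diff, cdk_kinases=("CDK1",))
        assert not out.loc["s1", "empirical"]

    def test_empirical_implies_theoretical(self):
        rng = np.random.default_rng(0)
        rows = {f"s{i}": (rng.random(),
                          rng.choice(["c_fast", "c_slow", "c_other"]),
                          rng.random(), rng.normal())
                for i in range(200)}
        probs, clusters, diff = _inputs(rows)
        out = predict_empirical_cdk(probs, {"CDK1": 0.5}, clusters, DYN,
                                    diff, cdk_kinases=("CDK1",))
        assert (out["theoretical"] | ~out["empirical"]).all()

    def test_matches_brute_force_conjunction_oracle(self):
        rng = np.random.default_rng(1)
        rows = {f"s{i}": (rng.random(),
                          rng.choice(["c_fast", "c_slow", "c_other"]),
                          rng.random(), rng.normal())
                for i in range(500)}
        probs, clusters, diff = _inputs(rows)
        out = predict_empirical_cdk(probs, {"CDK1": 0.5}, clusters, DYN,
                                    diff, fdr_cut=0.05,
                                    cdk_kinases=("CDK1",))
        oracle = {s for s, (p, c, fdr, lfc) in rows.items()
                  if p >= 0.5 and c in ("c_fast", "c_slow")
                  and fdr < 0.05 and lfc > 0}
        assert set(out.index[out["empirical"]]) == oracle

    def test_merged_probability_is_maximum(self):
        probs = pd.DataFrame({"CDK1": {"s1": 0.3}, "CDK2": {"s1": 0.8}})
        clusters = pd.Series({"s1": "c_fast"})
        diff = pd.DataFrame({"feature_id": ["s1"], "time_min": [90],
                             "log_fc": [1.0], "fdr": [0.01]})
        out = predict_empirical_cdk(probs, {"CDK1": 0.5, "CDK2": 0.5},
                                    clusters, DYN, diff)
        assert out.loc["s1", "cdk_probability"] == 0.8
        assert out.loc["s1", "best_kinase"] == "CDK2"

    def test_orphan_identifiers_rejected(self):
        probs, clusters, diff = _inputs({"s1": (0.9, "c_fast", 0.01, 1.0)})
        with pytest.raises(ValueError, match="missing"):
            predict_empirical_cdk(probs, {"CDK1": 0.5},
                                  clusters.drop("s1"), DYN, diff,
                                  cdk_kinases=("CDK1",))


def _random_flanks(rng, n, third_k_prob=None):
    flanks = []
    for _ in range(n):
        f = list(rng.choice(AA, 21))
        if third_k_prob is not None:
            f[13] = "K" if rng.random() < third_k_prob else f[13]
        flanks.append("".join(f))
    return flanks


class TestCompareClusterFrequencies:
    def test_null_clusters_centered_at_zero(self):
        rng = np.random.default_rng(2)
        fast = _random_flanks(rng, 150)
        slow = _random_flanks(rng, 150)
        table = compare_cluster_frequencies(fast, slow, seed=3)
        assert np.abs(table["mean_diff"]).max() < 0.2
        assert (table["mean_diff"].abs() < 3 * table["sd"]).mean() > 0.9

    def test_planted_lysine_enrichment_detected(self):
        rng = np.random.default_rng(4)
        fast = _random_flanks(rng, 150, third_k_prob=0.6)
        slow = _random_flanks(rng, 150, third_k_prob=0.1)
        table = compare_cluster_frequencies(fast, slow, seed=5)
        cell = table[(table["position"] == 3) & (table["residue"] == "K")]
        assert cell["mean_diff"].iloc[0] == pytest.approx(0.5, abs=0.15)
        assert cell["p_value"].iloc[0] < 0.001

    def test_degenerate_identical_single_sequences(self):
        flank = "A" * 10 + "S" + "A" * 10
        table = compare_cluster_frequencies([flank], [flank], seed=0)
        assert (table["mean_diff"] == 0).all()
        assert (table["sd"] == 0).all()
        assert table["p_value"].isna().all()

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            compare_cluster_frequencies(["A" * 21], ["A" * 21],
                                        n_resamples=1)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            compare_cluster_frequencies([], ["A" * 21])


def cy_oracle(sequence):
    """Brute-force sliding window over all triplets."""
    hits = []
    for i in range(len(sequence) - 2):
        if sequence[i] in "RK" and sequence[i + 2] in "LVI" \
                and sequence[i + 1] in AA:
            hits.append(i + 1)
    return hits


class TestFindCyMotifs:
    def test_single_match_right_of_site(self):
        res = find_cy_motifs("AAARALAAA", 1)
        assert res["matches"] == [4]
        assert res["left_distance"] is None
        assert res["right_distance"] == 3

    def test_no_basic_residue_no_match(self):
        res = find_cy_motifs("AAAGGGAAA", 5)
        assert res["matches"] == []
        assert res["left_distance"] is None
        assert res["right_distance"] is None

    def test_overlapping_matches_all_reported(self):
        res = find_cy_motifs("RKLVL", 5)
        assert res["matches"] == [1, 2]

    def test_site_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_cy_motifs("RKL", 4)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            seq = "".join(rng.choice(AA, rng.integers(5, 80)))
            site = int(rng.integers(1, len(seq) + 1))
            res = find_cy_motifs(seq, site)
            assert res["matches"] == cy_oracle(seq)

    def test_distance_table_nearest_on_each_side(self):
        seqs = {"P1": "RALAAASAAARAL"}
        sites = pd.DataFrame({"accession": ["P1"], "position": [7]},
                             index=["s1"])
        table = cy_distance_table(seqs, sites)
        assert table.loc["s1", "left_distance"] == 6    # motif at 1
        assert table.loc["s1", "right_distance"] == 4   # motif at 11
        assert table.loc["s1", "n_matches"] == 2


class TestDistanceDistributions:
    def test_identical_samples(self):
        res = compare_distance_distributions([1, 2, 3], [1, 2, 3])
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = compare_distance_distributions([1, 2, 3], [10, 11, 12])
        assert res["statistic"] == 1.0

    def test_matches_ecdf_supremum_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 50, 40).astype(float)
        b = rng.integers(0, 50, 25).astype(float)
        grid = np.unique(np.r_[a, b])
        ecdf_diff = max(abs((a <= g).mean() - (b <= g).mean())
                        for g in grid)
        res = compare_distance_distributions(a, b)
        assert res["statistic"] == pytest.approx(ecdf_diff, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distance_distributions([], [1.0])


class TestOra:
    def test_set_equal_to_background_p_one(self):
        bg = {f"g{i}" for i in range(50)}
        out = ora_hypergeometric({"g1", "g2"}, {"all": bg}, bg)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_tail_sum_oracle(self):
        bg = [f"g{i}" for i in range(100)]
        hits = set(bg[:10])
        gene_set = set(bg[:5])      # 5 of 5 in hits
        out = ora_hypergeometric(hits, {"S": gene_set}, bg)
        oracle = sum(stats.hypergeom.pmf(k, 100, 5, 10) for k in range(5, 6))
        assert out["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-9)

    def test_empty_hit_set_all_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        out = ora_hypergeometric(set(), {"S": {"g1", "g2"}}, bg)
        assert (out["p_value"] == 1.0).all()

    def test_bh_applied_across_sets(self):
        bg = [f"g{i}" for i in range(100)]
        sets = {"A": set(bg[:5]), "B": set(bg[50:60]), "C": set(bg[90:])}
        out = ora_hypergeometric(set(bg[:10]), sets, bg)
        from phosdyn.differential import bh_adjust
        np.testing.assert_allclose(out["fdr"],
                                   bh_adjust(out["p_value"]))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {}, set())

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"x"}, {}, {"y"})
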