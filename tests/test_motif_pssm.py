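"""Binomial residue scores, PSSM construction, scoring, logistic
calibration and ROC cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from phosdyn.containers import AMINO_ACIDS, ProteinRecord
from phosdyn.motif_pssm import (background_frequencies, build_pssm,
                                calibrate_logistic, count_matrix,
                                residue_score, roc_analysis, score_site,
                                score_sites)
from phosdyn.synth import (CDK_MOTIF, generate_proteome, plant_kinase_sites)
from phosdyn.containers import extract_flank


def binom_pmf_exact(k, n, p):
    return comb(n, k, exact=False) * p ** k * (1 - p) ** (n - k)


def residue_score_oracle(k_a, n, p_a):
    """Direct binomial tail summation, independent of scipy tails."""
    upper = sum(binom_pmf_exact(k, n, p_a) for k in range(k_a, n + 1))
    lower = sum(binom_pmf_exact(k, n, p_a) for k in range(0, k_a + 1))
    return -np.log10(upper / lower)


def auc_pair_counting(pos, neg):
    """Concordant-pair AUC: ties count one half."""
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestBackgroundFrequencies:
    def test_single_residue_proteome(self):
        prot = [ProteinRecord("P1", "A" * 100, np.full(100, 0.9))]
        bg = background_frequencies(prot)
        assert bg.freq["A"] > 0.8
        assert bg.freq.sum() == pytest.approx(1.0, abs=1e-12)
        assert (bg.freq > 0).all()

    def test_cutoff_excluding_everything_rejected(self):
        prot = [ProteinRecord("P1", "ACDE", np.array([0.5] * 4))]
        with pytest.raises(ValueError, match="cutoff"):
            background_frequencies(prot, cutoff=1.0)

    def test_manual_count_of_disordered_half(self):
        seq = "AAAACCCC"
        disorder = np.array([0.9] * 4 + [0.1] * 4)
        bg = background_frequencies([ProteinRecord("P1", seq, disorder)])
        assert bg.n_residues_used == 4
        # counts: A=4 (+1 pseudo), every other class pseudo 1; T = 4 + 20
        assert bg.freq["A"] == pytest.approx(5 / 24)
        assert bg.freq["C"] == pytest.approx(1 / 24)


class TestResidueScore:
    def test_hand_worked_single_trial(self):
        # N=1, K=1, p=0.5: P(k>=1)=0.5, P(k<=1)=1 -> -log10(0.5)
        assert residue_score(1, 1, 0.5) == pytest.approx(0.30103, abs=1e-5)

    def test_matches_direct_summation(self):
        assert residue_score(5, 10, 0.25) \
            == pytest.approx(residue_score_oracle(5, 10, 0.25), abs=1e-9)

    def test_expectation_scores_less_extreme_than_tails(self):
        mid = abs(residue_score(5, 10, 0.5))
        assert mid < abs(residue_score(9, 10, 0.5))
        assert mid < abs(residue_score(1, 10, 0.5))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(n=st.integers(1, 50), st_k=st.integers(0, 50),
           p=st.floats(0.01, 0.99))
    def test_oracle_agreement_random_triples(self, n, st_k, p):
        k = min(st_k, n)
        assert residue_score(k, n, p) \
            == pytest.approx(residue_score_oracle(k, n, p), abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(2, 40), p=st.floats(0.05, 0.95))
    def test_strictly_increasing_in_count(self, n, p):
        scores = [residue_score(k, n, p) for k in range(n + 1)]
        assert np.all(np.diff(scores) > 0)

    def test_printed_tail_variant_shifts_lower_bound(self):
        strict = residue_score(3, 10, 0.3)
        variant = residue_score(3, 10, 0.3, lower_tail_exclusive=True)
        assert variant < strict  # P(k<=K-1) < P(k<=K)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            residue_score(5, 3, 0.5)
        with pytest.raises(ValueError):
            residue_score(1, 3, 1.0)


class TestBuildPssm:
    def _background(self):
        prot = generate_proteome(30, (300, 500), seed=0)
        return background_frequencies(prot)

    def test_degenerate_training_set_all_alanine(self):
        flank = "A" * 10 + "S" + "A" * 10
        ann = pd.DataFrame({"kinase": "K1",
                            "accession": [f"P{i}" for i in range(20)],
                            "position": 50, "curation_effort": 3})
        flank_of = {(f"P{i}", 50): flank for i in range(20)}
        models = build_pssm(ann, flank_of, self._background())
        scores = models["K1"].scores
        flank_positions = [p for p in scores.index if p != 0]
        assert (scores.loc[flank_positions, "A"] > 0).all()
        others = [aa for aa in AMINO_ACIDS if aa != "A"]
        assert (scores.loc[flank_positions, others] < 0).all().all()

    def test_too_few_sites_skipped(self):
        flank = "A" * 10 + "S" + "A" * 10
        ann = pd.DataFrame({"kinase": ["K1"] * 19 + ["K2"] * 20,
                            "accession": [f"P{i}" for i in range(39)],
                            "position": 50, "curation_effort": 3})
        flank_of = {(f"P{i}", 50): flank for i in range(39)}
        models = build_pssm(ann, flank_of, self._background())
        assert set(models) == {"K2"}

    def test_low_curation_sites_excluded(self):
        flank = "A" * 10 + "S" + "A" * 10
        ann = pd.DataFrame({"kinase": "K1",
                            "accession": [f"P{i}" for i in range(20)],
                            "position": 50,
                            "curation_effort": [3] * 10 + [2] * 10})
        flank_of = {(f"P{i}", 50): flank for i in range(20)}
        with pytest.raises(ValueError, match="no kinase"):
            build_pssm(ann, flank_of, self._background())

    def test_planted_motif_recovered_at_plus_one_proline(self):
        proteome = generate_proteome(60, (300, 500), seed=2)
        ann, edited = plant_kinase_sites(proteome, {"CDK": CDK_MOTIF}, 80,
                                         seed=3)
        seq_of = {p.accession: p.sequence for p in edited}
        flank_of = {(a, p): extract_flank(seq_of[a], p)
                    for a, p in zip(ann["accession"], ann["position"])}
        bg = background_frequencies(edited)
        models = build_pssm(ann, flank_of, bg)
        scores = models["CDK"].scores
        off_center = scores.drop(index=0)
        idx = np.unravel_index(np.argmax(off_center.to_numpy()),
                               off_center.shape)
        assert (off_center.index[idx[0]], off_center.columns[idx[1]]) \
            == (1, "P")

    def test_pad_characters_not_counted(self):
        counts, totals = count_matrix(["_" * 10 + "S" + "A" * 10])
        assert totals.loc[-1] == 0 and totals.loc[1] == 1
        assert counts.loc[1, "A"] == 1


class TestScoreSite:
    def _model(self, scores):
        from phosdyn.motif_pssm import BackgroundFreqs, PssmModel
        freq = pd.Series(1 / 20, index=list(AMINO_ACIDS))
        return PssmModel(kinase="K", scores=scores, n_training_sites=20,
                         background=BackgroundFreqs(freq, 100))

    def test_zero_matrix_scores_zero(self):
        scores = pd.DataFrame(0.0, index=range(-10, 11),
                              columns=list(AMINO_ACIDS))
        assert score_site("A" * 10 + "S" + "A" * 10,
                          self._model(scores)) == 0.0

    def test_argmax_flank_reaches_row_max_sum(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(0, 1, (21, 20)),
                              index=range(-10, 11),
                              columns=list(AMINO_ACIDS))
        model = self._model(scores)
        best_flank = "".join(scores.loc[p].idxmax() for p in range(-10, 11))
        assert score_site(best_flank, model) \
            == pytest.approx(scores.max(axis=1).sum(), abs=1e-12)

    def test_matches_lookup_sum_oracle(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(rng.normal(0, 1, (21, 20)),
                              index=range(-10, 11),
                              columns=list(AMINO_ACIDS))
        model = self._model(scores)
        flank = "".join(rng.choice(list(AMINO_ACIDS), 21))
        expected = sum(scores.loc[p, ch]
                       for p, ch in zip(range(-10, 11), flank))
        assert score_site(flank, model) == pytest.approx(expected, abs=1e-12)

    def test_additivity_over_matrices(self):
        rng = np.random.default_rng(5)
        s1 = pd.DataFrame(rng.normal(0, 1, (21, 20)), index=range(-10, 11),
                          columns=list(AMINO_ACIDS))
        s2 = pd.DataFrame(rng.normal(0, 1, (21, 20)), index=range(-10, 11),
                          columns=list(AMINO_ACIDS))
        flank = "".join(rng.choice(list(AMINO_ACIDS), 21))
        total = score_site(flank, self._model(s1 + s2))
        assert total == pytest.approx(
            score_site(flank, self._model(s1))
            + score_site(flank, self._model(s2)), abs=1e-12)

    def test_pad_contributes_zero(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(0, 1, (21, 20)),
                              index=range(-10, 11),
                              columns=list(AMINO_ACIDS))
        model = self._model(scores)
        padded = "_" * 10 + "S" + "A" * 10
        expected = scores.loc[0, "S"] + sum(scores.loc[p, "A"]
                                            for p in range(1, 11))
        assert score_site(padded, model) == pytest.approx(expected,
                                                          abs=1e-12)

    def test_invalid_residue_error_names_position(self):
        scores = pd.DataFrame(0.0, index=range(-10, 11),
                              columns=list(AMINO_ACIDS))
        with pytest.raises(ValueError, match="position -10"):
            score_site("B" + "A" * 20, self._model(scores))


class TestCalibration:
    def test_separable_scores_saturate_probabilities(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(10, 0.5, 100)
        neg = rng.normal(-10, 0.5, 100)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        cal = calibrate_logistic(scores, labels, seed=1)
        prob = 1 / (1 + np.exp(-(cal["beta0"] + cal["beta1"] * scores)))
        assert (prob[:100] > 0.99).all() and (prob[100:] < 0.01).all()

    def test_probability_half_at_decision_boundary(self):
        rng = np.random.default_rng(8)
        scores = np.r_[rng.normal(1, 1, 200), rng.normal(-1, 1, 200)]
        labels = np.r_[np.ones(200, bool), np.zeros(200, bool)]
        cal = calibrate_logistic(scores, labels, seed=2)
        boundary = -cal["beta0"] / cal["beta1"]
        p = 1 / (1 + np.exp(-(cal["beta0"] + cal["beta1"] * boundary)))
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_classes_give_near_zero_intercept(self):
        rng = np.random.default_rng(9)
        scores = np.r_[rng.normal(1, 1, 3000), rng.normal(-1, 1, 3000)]
        labels = np.r_[np.ones(3000, bool), np.zeros(3000, bool)]
        cal = calibrate_logistic(scores, labels, seed=3)
        assert abs(cal["beta0"]) < 0.2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            calibrate_logistic(np.ones(10), np.ones(10, bool))

    def test_downsampling_balances_training(self):
        rng = np.random.default_rng(10)
        scores = np.r_[rng.normal(1, 1, 20), rng.normal(-1, 1, 500)]
        labels = np.r_[np.ones(20, bool), np.zeros(500, bool)]
        cal = calibrate_logistic(scores, labels, seed=4)
        assert cal["n_train_balanced"] == 2 * 16  # 80% of 20 per class


class TestRoc:
    def test_perfect_ranking(self):
        res = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res["auc"] == 1.0
        assert res["cutoff"] > 0.2

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        probs = rng.random(4000)
        labels = rng.random(4000) < 0.5
        res = roc_analysis(probs, labels)
        assert abs(res["auc"] - 0.5) < 0.05

    def test_worked_two_vs_two_with_tie(self):
        pos, neg = [0.9, 0.7], [0.4, 0.7]
        res = roc_analysis(pos + neg, [1, 1, 0, 0])
        expected = auc_pair_counting(pos, neg)
        assert expected == 0.875
        assert res["auc"] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.random(8)
        neg = rng.random(8)
        res = roc_analysis(np.r_[pos, neg],
                           np.r_[np.ones(8, bool), np.zeros(8, bool)])
        assert res["auc"] == pytest.approx(auc_pair_counting(pos, neg),
                                           abs=1e-12)

    def test_cutoff_maximizes_youden(self):
        probs = np.array([0.9, 0.8, 0.6, 0.4, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0], bool)
        res = roc_analysis(probs, labels)
        grid = np.unique(probs)
        js = [(probs[labels] >= c).mean() - (probs[~labels] >= c).mean()
              for c in grid]
        assert res["youden_j"] == pytest.approx(max(js), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.9], [1, 1])


class TestPipelineRecovery:
    def test_planted_motif_held_out_auc(self, small_sim):
        """PSSM built on planted CDK substrates separates them from
        decoys with high held-out AUC."""
        fm = small_sim.phospho.feature_meta
        ann = small_sim.annotations
        bg = background_frequencies(small_sim.proteome)
        flank_of = {(r["accession"], r["position"]): r["flank"]
                    for _, r in fm.iterrows()}
        models = build_pssm(ann, flank_of, bg)
        model = models["CDK1"]
        is_cdk = fm["kinase"].isin(["CDK1", "CDK2"])
        raw = score_sites(fm["flank"].tolist(), model)
        cal = calibrate_logistic(raw, is_cdk.to_numpy(), seed=5)
        mask = cal["test_mask"]
        assert cal["test_auc"] >= 0.95
        assert mask.sum() < len(fm)  # genuinely held out
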