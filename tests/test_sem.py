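"""Normalization, QC statistic, sequence scoring and matrix analytics."""

import itertools
import math

import numpy as np
import pytest

from methylsem import sem as sm
from methylsem.io import ALPHABET, SEMResult


def make_sem(scores, endogenous=10.0, scrambled=-3.0, stderr_value=0.1):
    scores = np.asarray(scores, dtype=float)
    stderr = np.where(np.isnan(scores), np.nan, stderr_value)
    totals = np.where(np.isnan(scores), 0, 50).astype(int)
    return SEMResult(
        scores=scores,
        stderr=stderr,
        totals=totals,
        endogenous_baseline=endogenous,
        scrambled_baseline=scrambled,
    )


class TestNormalize:
    def _normalize(self, raw, endogenous=8.0, scrambled=-3.0):
        raw = np.asarray(raw, dtype=float)
        stderr = np.where(np.isnan(raw), np.nan, 0.5)
        totals = np.where(np.isnan(raw), 0, 10).astype(int)
        return sm.normalize(raw, stderr, totals, endogenous, scrambled)

    def test_baseline_maps_to_zero_and_log2_arithmetic(self):
        raw = np.full((1, 6), 8.0)
        raw[0, 1] = 16.0
        raw[0, 2] = 2.0
        result = self._normalize(raw)
        assert result.scores[0, 0] == pytest.approx(0.0)
        assert result.scores[0, 1] == pytest.approx(1.0)
        assert result.scores[0, 2] == pytest.approx(-2.0)

    def test_zero_raw_floors_at_scrambled_minus_one(self):
        raw = np.full((1, 6), 8.0)
        raw[0, 3] = 0.0
        result = self._normalize(raw, scrambled=-3.0)
        assert result.scores[0, 3] == pytest.approx(-4.0)

    def test_nan_propagates(self):
        raw = np.full((1, 6), 8.0)
        raw[0, 4] = math.nan
        result = self._normalize(raw)
        assert math.isnan(result.scores[0, 4])

    def test_monotone_in_raw_signal(self, rng):
        raw = rng.uniform(0.5, 40.0, size=(3, 6))
        result = self._normalize(raw)
        order_raw = np.argsort(raw.ravel())
        order_score = np.argsort(result.scores.ravel())
        assert np.array_equal(order_raw, order_score)

    def test_denormalize_round_trip(self, rng):
        raw = rng.uniform(0.5, 40.0, size=(2, 6))
        result = self._normalize(raw)
        assert np.allclose(sm.denormalize(result), raw, atol=1e-9)

    def test_rejects_bad_baseline(self):
        with pytest.raises(ValueError):
            self._normalize(np.full((1, 6), 8.0), endogenous=0.0)


class TestQCStatistic:
    def test_same_distribution_fails(self, rng):
        a = rng.normal(10, 2, size=5000)
        b = rng.normal(10, 2, size=5000)
        report = sm.qc_statistic(a, b, seed=1)
        assert report.statistic < 3.15
        assert not report.passed
        assert report.statistic == pytest.approx(0.3, abs=0.25)  # -log10(~0.5)

    def test_strong_shift_passes(self, rng):
        a = rng.normal(20, 2, size=5000)
        b = rng.normal(10, 2, size=5000)
        report = sm.qc_statistic(a, b, seed=1)
        assert report.statistic > 3.15 and report.passed

    def test_identical_constants_give_statistic_zero(self):
        report = sm.qc_statistic([3.0] * 10, [3.0] * 10, seed=0)
        assert report.statistic == 0.0 and not report.passed

    def test_scale_invariance(self, rng):
        a = rng.lognormal(2, 0.5, size=2000)
        b = rng.lognormal(1, 0.5, size=2000)
        r1 = sm.qc_statistic(a, b, seed=7)
        r2 = sm.qc_statistic(a * 137.0, b * 137.0, seed=7)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            sm.qc_statistic([], [1.0])


class TestScoreSequence:
    def test_all_zero_matrix_scores_zero(self):
        zero = make_sem(np.zeros((4, 6)))
        assert sm.score_sequence(zero, "ACGT")[0] == 0.0
        assert sm.score_sequence(zero, "AMWT")[0] == 0.0

    def test_hand_computed_mixed_alphabet(self, rng):
        scores = rng.normal(size=(3, 6))
        semr = make_sem(scores)
        value, undefined = sm.score_sequence(semr, "AMG")
        expected = scores[0, 0] + scores[1, 4] + scores[2, 2]
        assert value == pytest.approx(expected)
        assert undefined == []

    def test_argmax_sequence_is_sum_of_column_maxima(self, rng):
        scores = rng.normal(size=(5, 6))
        semr = make_sem(scores)
        best = "".join(ALPHABET[j] for j in np.argmax(scores, axis=1))
        value, _ = sm.score_sequence(semr, best)
        assert value == pytest.approx(scores.max(axis=1).sum())

    def test_undefined_cell_reports_position(self):
        scores = np.zeros((3, 6))
        scores[1, 4] = math.nan
        semr = make_sem(scores)
        value, undefined = sm.score_sequence(semr, "AMA")
        assert math.isnan(value) and undefined == [2]

    def test_illegal_letter_and_length(self):
        semr = make_sem(np.zeros((3, 6)))
        with pytest.raises(ValueError, match="illegal"):
            sm.score_sequence(semr, "AXA")
        with pytest.raises(ValueError, match="length"):
            sm.score_sequence(semr, "AAAA")

    def test_double_variant_additivity_exhaustive(self, rng):
        """Any double variant's score equals the consensus score plus the two
        single-variant deltas, for every double variant of an L=5 matrix."""
        scores = rng.normal(size=(5, 6))
        semr = make_sem(scores)
        consensus = "".join(ALPHABET[j] for j in np.argmax(scores[:, :4], axis=1))
        base, _ = sm.score_sequence(semr, consensus)
        for i, j in itertools.combinations(range(5), 2):
            for a in ALPHABET:
                for b in ALPHABET:
                    seq = list(consensus)
                    seq[i], seq[j] = a, b
                    double, _ = sm.score_sequence(semr, "".join(seq))
                    da = scores[i, ALPHABET.index(a)] - scores[i, ALPHABET.index(consensus[i])]
                    db = scores[j, ALPHABET.index(b)] - scores[j, ALPHABET.index(consensus[j])]
                    assert double == pytest.approx(base + da + db, abs=1e-9)


class TestSensitivity:
    def test_identical_channels_have_zero_differences(self):
        scores = np.zeros((4, 6))
        frame = sm.sensitivity_profile(make_sem(scores))
        assert (frame.cm_diff == 0).all()
        assert (frame.gw_diff == 0).all()
        assert frame.attrs["cm_prop_sensitive"] == 0.0

    def test_known_difference_magnitude(self):
        scores = np.zeros((3, 6))
        scores[1, 1] = 0.0  # C
        scores[1, 4] = -2.0  # M
        frame = sm.sensitivity_profile(make_sem(scores))
        assert frame.cm_diff[1] == pytest.approx(2.0)

    def test_planted_sensitive_positions_rank_highest(self):
        scores = np.zeros((6, 6))
        scores[1, 4] = -1.8  # M at position 2
        scores[4, 5] = 1.5   # W at position 5
        frame = sm.sensitivity_profile(make_sem(scores, stderr_value=0.05))
        combined = frame.cm_diff + frame.gw_diff
        top2 = set(np.argsort(combined.values)[-2:])
        assert top2 == {1, 4}
        assert frame.cm_sensitive[1] and frame.gw_sensitive[4]

    def test_methylation_effect_increases_mean_difference(self):
        """Across 10 seeds, matrices with planted M/W offsets always show a
        larger mean |C-M| than effect-free matrices."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.normal(0, 0.05, size=(6, 6))
            with_effect = base.copy()
            with_effect[:, 4] += rng.choice([-1.5, 1.5], size=6)
            f_base = sm.sensitivity_profile(make_sem(base))
            f_eff = sm.sensitivity_profile(make_sem(with_effect))
            assert f_eff.attrs["cm_mean_diff"] > f_base.attrs["cm_mean_diff"]


class TestCompare:
    def test_self_comparison_r2_one(self, rng):
        semr = make_sem(rng.normal(size=(5, 6)))
        stats = sm.compare_sems(semr, semr)
        assert stats["r2"] == pytest.approx(1.0)

    def test_negated_matrix_is_sign_blind(self, rng):
        scores = rng.normal(size=(5, 6))
        stats = sm.compare_sems(make_sem(scores), make_sem(-scores))
        assert stats["r2"] == pytest.approx(1.0)
        assert stats["r"] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        a = make_sem(rng.normal(size=(20, 6)))
        b = make_sem(rng.normal(size=(20, 6)))
        assert sm.compare_sems(a, b)["r2"] < 0.1

    def test_mw_subset_uses_only_methylated_columns(self, rng):
        scores_a = rng.normal(size=(5, 6))
        scores_b = scores_a.copy()
        scores_b[:, :4] = rng.normal(size=(5, 4))  # scramble ACGT only
        stats = sm.compare_sems(make_sem(scores_a), make_sem(scores_b), subset="MW")
        assert stats["r2"] == pytest.approx(1.0)
        assert stats["n"] == 10

    def test_too_few_shared_cells_rejected(self):
        scores = np.full((4, 6), math.nan)
        scores[0, 0] = 0.0
        a = make_sem(scores)
        with pytest.raises(ValueError, match=">= 3"):
            sm.compare_sems(a, a)

    def test_fisher_comparison_direction(self):
        p_strong = sm.compare_correlations(0.95, 50, 0.2, 50)
        p_equal = sm.compare_correlations(0.5, 50, 0.5, 50)
        assert p_strong < 0.001
        assert p_equal == pytest.approx(0.5)


class TestKmerScoreVsSignal:
    def _observations(self, semr, rng, n_kmers=12, n_occ=60):
        from methylsem.alignment import AlignedObservation

        obs = {}
        for _ in range(n_kmers):
            kmer = "".join(rng.choice(list("ACGT"), size=semr.length))
            score, und = sm.score_sequence(semr, kmer)
            if und:
                continue
            value = semr.endogenous_baseline * 2.0**score
            obs[kmer] = [
                AlignedObservation("c", i, "+", kmer, signal=value)
                for i in range(n_occ)
            ]
        return obs

    def test_exponential_signal_gives_high_r2(self, rng):
        semr = make_sem(rng.normal(0, 1, size=(5, 6)), scrambled=-8.0)
        table, r2 = sm.kmer_score_vs_signal(semr, self._observations(semr, rng))
        assert r2 >= 0.95
        assert (table.n >= 50).all()

    def test_min_occurrence_filter_error_path(self, rng):
        semr = make_sem(rng.normal(size=(5, 6)))
        obs = self._observations(semr, rng, n_occ=10)
        with pytest.raises(ValueError, match="occurrences"):
            sm.kmer_score_vs_signal(semr, obs, min_occurrences=50)

    def test_clamping_at_scrambled_baseline(self, rng):
        scores = np.zeros((4, 6))
        scores[0, 0] = -20.0
        semr = make_sem(scores, scrambled=-3.0)
        from methylsem.alignment import AlignedObservation

        obs = {"AAAA": [AlignedObservation("c", i, "+", "AAAA", signal=1.0)
                        for i in range(60)],
               "CAAA": [AlignedObservation("c", i, "+", "CAAA", signal=5.0)
                        for i in range(60)]}
        table, _ = sm.kmer_score_vs_signal(semr, obs)
        assert table.set_index("kmer").loc["AAAA", "score"] == pytest.approx(-3.0)
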