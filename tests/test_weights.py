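"""Tests for the six annotator-weighting strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crowdedda as cd
from crowdedda.weights import MISSING, MajorityLabels, soft_scores

from conftest import make_gaussian_classes


class TestScoring:
    def test_perfect_agreement(self):
        ref = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1])
        Y = np.column_stack([ref, np.roll(ref, 1)])
        s = cd.score_against_reference(Y, ref)
        assert s[0] == 10

    def test_worked_example_scores(self, label_matrix_3x5):
        mv = cd.majority_labels(label_matrix_3x5)
        np.testing.assert_array_equal(mv.labels, [1, 3, MISSING])
        s = cd.score_against_reference(label_matrix_3x5, mv.labels)
        np.testing.assert_array_equal(s, [2, 1, 2, 0, 2])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        Y = rng.integers(1, 4, size=(20, 3))
        ref = rng.integers(1, 4, size=20)
        ref[rng.random(20) < 0.3] = MISSING
        expected = np.zeros(3, dtype=int)
        for n in range(20):
            for m in range(3):
                if ref[n] != MISSING and Y[n, m] == ref[n]:
                    expected[m] += 1
        np.testing.assert_array_equal(cd.score_against_reference(Y, ref), expected)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 30))
    def test_additive_over_disjoint_row_subsets(self, seed, n):
        rng = np.random.default_rng(seed)
        Y = rng.integers(1, 4, size=(n, 4))
        ref = rng.integers(1, 4, size=n)
        cut = n // 2
        total = cd.score_against_reference(Y, ref)
        parts = (cd.score_against_reference(Y[:cut], ref[:cut])
                 + cd.score_against_reference(Y[cut:], ref[cut:]))
        np.testing.assert_array_equal(total, parts)


class TestRescale:
    def test_worked_example_weights(self, label_matrix_3x5):
        w = cd.weights_mv(label_matrix_3x5)
        np.testing.assert_allclose(w.w, np.array([2, 1, 2, 0, 2]) / 7, atol=1e-15)

    def test_equal_scores(self):
        np.testing.assert_array_equal(cd.rescale_scores([5, 5]).w, [0.5, 0.5])

    def test_zero_total_falls_back_to_equal(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="crowdedda.weights"):
            w = cd.rescale_scores([0, 0, 0])
        np.testing.assert_allclose(w.w, [1 / 3, 1 / 3, 1 / 3])
        assert any("equal weights" in r.message for r in caplog.records)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            cd.rescale_scores([1, -1])


class TestPGT:
    def test_right_vs_wrong_annotator(self):
        y_true = np.array([1, 2, 3, 1])
        Y2 = np.column_stack([y_true, (y_true % 3) + 1])
        w = cd.weights_pgt(Y2, y_true)
        np.testing.assert_array_equal(w.w, [1.0, 0.0])
        assert w.strategy == "PGT"

    def test_hand_counted_4x2(self):
        # annotator 1 agrees with truth on rows 1-3 (3 times), annotator 2
        # only on row 1, so the weights are (3/4, 1/4)
        y_true = np.array([1, 1, 2, 2])
        Y2 = np.array([[1, 1], [1, 3], [2, 3], [3, 3]])
        w = cd.weights_pgt(Y2, y_true)
        np.testing.assert_allclose(w.w, [0.75, 0.25])

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            cd.weights_pgt(np.empty((0, 2), dtype=int), np.empty(0, dtype=int))


class TestEN:
    def test_two_annotators_09(self):
        w = cd.weights_en(["expert", "novice"], {"expert": 0.9, "novice": 0.1})
        np.testing.assert_allclose(w.w, [0.9, 0.1])

    def test_two_annotators_07(self):
        w = cd.weights_en(["expert", "novice"], {"expert": 0.7, "novice": 0.3})
        np.testing.assert_allclose(w.w, [0.7, 0.3])

    def test_four_experts_three_novices_default_mass(self):
        w = cd.weights_en(["expert"] * 4 + ["novice"] * 3)
        np.testing.assert_allclose(w.w, [0.2] * 4 + [0.2 / 3] * 3)

    def test_empty_tier_with_mass_raises(self):
        with pytest.raises(ValueError, match="no annotators"):
            cd.weights_en(["novice", "novice"], {"expert": 0.8, "novice": 0.2})


class TestEqual:
    @pytest.mark.parametrize("M", [1, 7, 100])
    def test_uniform_and_normalized(self, M):
        w = cd.weights_equal(M)
        np.testing.assert_allclose(w.w, np.full(M, 1.0 / M))
        assert w.w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            cd.weights_equal(0)


class TestMajorityLabels:
    def test_plain_majority_worked_example(self, label_matrix_3x5):
        mv = cd.majority_labels(label_matrix_3x5)
        np.testing.assert_array_equal(mv.labels, [1, 3, MISSING])
        assert bool(mv.tie[2])

    def test_stricter_threshold_four_of_five(self, label_matrix_3x5):
        mv = cd.majority_labels(label_matrix_3x5, agreement_threshold=0.8)
        np.testing.assert_array_equal(mv.labels, [1, MISSING, MISSING])
        w = cd.weights_mv(label_matrix_3x5, agreement_threshold=0.8)
        np.testing.assert_array_equal(w.s, [1, 1, 1, 0, 1])
        np.testing.assert_allclose(w.w, [0.25, 0.25, 0.25, 0.0, 0.25])

    def test_unanimous_annotators(self):
        Y = np.tile(np.array([[2], [1], [3]]), (1, 5))
        mv = cd.majority_labels(Y, agreement_threshold=1.0)
        np.testing.assert_array_equal(mv.labels, [2, 1, 3])
        w = cd.weights_mv(Y)
        np.testing.assert_allclose(w.w, np.full(5, 0.2))

    def test_all_rows_deadlocked_falls_back_equal(self, caplog):
        import logging

        Y = np.array([[1, 2], [3, 1], [2, 3]])
        with caplog.at_level(logging.WARNING, logger="crowdedda.weights"):
            w = cd.weights_mv(Y, G=3)
        np.testing.assert_allclose(w.w, [0.5, 0.5])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(21)
        Y = rng.integers(1, 4, size=(40, 7))
        s_loose = cd.weights_mv(Y, agreement_threshold=3 / 7).s
        s_strict = cd.weights_mv(Y, agreement_threshold=6 / 7).s
        assert np.all(s_strict <= s_loose)


class TestIterative:
    def test_single_observation_scores_hard_and_soft(self, single_obs_posteriors):
        z, labels, est = single_obs_posteriors
        hard = cd.score_against_reference(labels, est)
        np.testing.assert_array_equal(hard, [1, 1, 0])
        soft = soft_scores(labels, est, z)
        np.testing.assert_allclose(soft, [0.8, 0.5, 0.0])

    def test_identical_annotators_converge_immediately(self, toy8):
        X, y = toy8
        Y = np.tile(y[:, None], (1, 3))
        base = [cd.fit_edda(X, y, "EEE")] * 3
        res = cd.iterative_weights(X, Y, base, variant=1)
        assert res.converged
        assert res.n_iterations == 1
        np.testing.assert_allclose(res.weights.w, [1 / 3, 1 / 3, 1 / 3])

    @pytest.mark.parametrize("variant", [1, 2])
    def test_max_iter_zero_returns_mv_initialized_weights(self, toy8, variant):
        X, y = toy8
        rng = np.random.default_rng(4)
        Y = np.tile(y[:, None], (1, 3))
        flip = rng.random(Y.shape) < 0.25
        Y[flip] = rng.integers(1, 3, size=int(flip.sum()))
        base = [cd.fit_edda(X, Y[:, m], "EEE") for m in range(3)]
        res = cd.iterative_weights(X, Y, base, variant=variant, max_iter=0)
        mv = cd.majority_labels(Y, G=2)
        ref = mv.labels.copy()
        if np.any(ref == MISSING):  # deadlocks resolve to the lowest tied class
            counts = np.stack([(Y == g).sum(axis=1) for g in (1, 2)], axis=1)
            low = np.argmax(counts == counts.max(axis=1, keepdims=True), axis=1) + 1
            ref = np.where(ref == MISSING, low, ref)
        if variant == 1:
            expected = cd.score_against_reference(Y, ref)
        else:
            post = np.stack([cd.posterior(b, X) for b in base])
            expected = soft_scores(Y, ref, post)
        np.testing.assert_allclose(res.weights.w, expected / expected.sum())

    @pytest.mark.parametrize("variant", [1, 2])
    def test_matches_step_by_step_trace_oracle(self, variant):
        # independent re-implementation of the iterative loop on a small
        # synthetic instance with noisy annotators
        X, y = make_gaussian_classes(17, [[2, 2], [0, 0], [-2, -2]], 20)
        rng = np.random.default_rng(18)
        Y = np.tile(y[:, None], (1, 4))
        flip = rng.random(Y.shape) < 0.3
        Y[flip] = rng.integers(1, 4, size=int(flip.sum()))
        base = [cd.fit_edda(X, Y[:, m], "EEE") for m in range(4)]
        res = cd.iterative_weights(X, Y, base, variant=variant, max_iter=100)
        assert res.converged
        assert res.n_iterations <= 100

        post = np.stack([cd.posterior(b, X) for b in base])
        mv = cd.majority_labels(Y, G=3)
        y_hat = mv.labels.copy()
        counts = np.stack([(Y == g).sum(axis=1) for g in (1, 2, 3)], axis=1)
        low = np.argmax(counts == counts.max(axis=1, keepdims=True), axis=1) + 1
        y_hat = np.where(y_hat == MISSING, low, y_hat)
        for _ in range(100):
            if variant == 1:
                s = cd.score_against_reference(Y, y_hat).astype(float)
            else:
                s = soft_scores(Y, y_hat, post)
            w = s / s.sum()
            ens = cd.stack(base, cd.WeightVector(w))
            y_new = cd.ensemble_predict(ens, X)[1]
            if np.array_equal(y_new, y_hat):
                break
            y_hat = y_new
        np.testing.assert_allclose(res.weights.w, w, atol=1e-15)
        np.testing.assert_array_equal(res.labels, y_hat)

    def test_negative_max_iter_raises(self, toy8):
        X, y = toy8
        base = [cd.fit_edda(X, y, "EEE")]
        with pytest.raises(ValueError):
            cd.iterative_weights(X, y[:, None], base, max_iter=-1)


class TestSimplexInvariant:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_every_strategy_returns_simplex_weights(self, seed):
        rng = np.random.default_rng(seed)
        N, M, G = 15, 5, 3
        Y = rng.integers(1, G + 1, size=(N, M))
        y_true = rng.integers(1, G + 1, size=N)
        for w in (
            cd.weights_pgt(Y, y_true),
            cd.weights_en(["expert", "expert", "novice", "novice", "novice"]),
            cd.weights_equal(M),
            cd.weights_mv(Y, G=G),
            cd.weights_mv(Y, agreement_threshold=0.8, G=G),
        ):
            assert np.all(w.w >= 0)
            assert w.w.sum() == pytest.approx(1.0, abs=1e-12)
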