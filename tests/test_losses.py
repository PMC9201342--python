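"""Loss and schedule oracles: hand-derived values, explicit-loop equivalence,
and the qualitative behavior of the decay schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bbuda.losses import (
    ScheduleState,
    alpha_schedule,
    cross_entropy_loss,
    emd_lambda,
    entropy_loss,
    kl_distillation_loss,
    mixup_pseudo_label,
    total_loss,
)
from conftest import random_prob_maps


def loop_kl(q, y):
    """Brute-force per-pixel KL mean, explicit loops."""
    n, c, h, w = q.shape
    total = 0.0
    for i in range(n):
        for r in range(h):
            for s in range(w):
                for k in range(c):
                    total += q[i, k, r, s] * math.log(q[i, k, r, s] / y[i, k, r, s])
    return total / (n * h * w)


def loop_entropy(q):
    n, c, h, w = q.shape
    total = 0.0
    for i in range(n):
        for r in range(h):
            for s in range(w):
                for k in range(c):
                    total -= q[i, k, r, s] * math.log(q[i, k, r, s])
    return total / (n * h * w)


class TestCrossEntropy:
    def test_uniform_prediction_four_classes(self):
        pred = np.full((1, 4, 4, 4), 0.25)
        label = np.zeros((1, 4, 4), dtype=int)
        # as-written CE carries a 1/C factor: (1/4) ln 4 per pixel
        assert cross_entropy_loss(pred, label) == pytest.approx(math.log(4) / 4,
                                                                rel=1e-12)

    def test_unscaled_variant_is_classic_ce(self):
        pred = np.full((1, 4, 4, 4), 0.25)
        label = np.zeros((1, 4, 4), dtype=int)
        assert cross_entropy_loss(pred, label, scale_by_classes=False) == \
            pytest.approx(math.log(4), rel=1e-12)

    def test_perfect_prediction_is_zero(self):
        label = np.array([[[0, 1], [2, 3]]])
        pred = np.transpose(np.eye(4)[label], (0, 3, 1, 2))
        assert cross_entropy_loss(pred, label) < 1e-6

    def test_loss_decreases_as_mass_moves_to_truth(self):
        label = np.zeros((1, 2, 2), dtype=int)
        losses = []
        for p_true in (0.4, 0.6, 0.8, 0.95):
            pred = np.empty((1, 4, 2, 2))
            pred[:, 0] = p_true
            pred[:, 1:] = (1 - p_true) / 3
            losses.append(cross_entropy_loss(pred, label))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_invalid_label_raises(self):
        pred = np.full((1, 4, 2, 2), 0.25)
        with pytest.raises(ValueError):
            cross_entropy_loss(pred, np.full((1, 2, 2), 7))

    def test_gradient_matches_finite_difference(self, rng):
        pred = random_prob_maps(rng, n=1, c=3, h=2, w=2)
        label = rng.integers(0, 3, size=(1, 2, 2))
        val, grad = cross_entropy_loss(pred, label, return_grad=True)
        eps = 1e-7
        for k in range(3):
            bumped = pred.copy()
            bumped[0, k, 0, 0] += eps
            num = (cross_entropy_loss(bumped, label) - val) / eps
            assert num == pytest.approx(grad[0, k, 0, 0], rel=1e-4, abs=1e-8)


class TestSchedules:
    def test_lambda_starts_at_lambda0(self):
        assert emd_lambda(ScheduleState(iteration=0, total_epochs=10)) == 1.0

    def test_lambda_at_one_epoch_is_exp_minus_one(self):
        state = ScheduleState(iteration=1, total_epochs=10)
        assert emd_lambda(state) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_lambda_strictly_decreasing_to_zero(self):
        vals = [emd_lambda(ScheduleState(iteration=i, total_epochs=100))
                for i in range(30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-12

    def test_alpha_endpoints_and_midpoint(self):
        assert alpha_schedule(ScheduleState(iteration=0, total_epochs=10)) == 5.0
        assert alpha_schedule(ScheduleState(iteration=10, total_epochs=10)) == 0.0
        assert alpha_schedule(ScheduleState(iteration=5, total_epochs=10)) == 2.5

    def test_alpha_constant_and_zero_modes(self):
        for i in (0, 3, 9):
            st_c = ScheduleState(iteration=i, total_epochs=10, alpha_mode="constant")
            st_z = ScheduleState(iteration=i, total_epochs=10, alpha_mode="zero")
            assert alpha_schedule(st_c) == 5.0
            assert alpha_schedule(st_z) == 0.0


class TestMixupPseudoLabel:
    def test_endpoints_return_inputs_exactly(self, rng):
        src = random_prob_maps(rng)
        tgt = random_prob_maps(rng)
        np.testing.assert_array_equal(mixup_pseudo_label(src, tgt, 1.0), src)
        np.testing.assert_array_equal(mixup_pseudo_label(src, tgt, 0.0), tgt)

    def test_halfway_mix_of_one_hots(self):
        src = np.zeros((1, 2, 1, 1))
        src[0, 0] = 1.0
        tgt = np.zeros((1, 2, 1, 1))
        tgt[0, 1] = 1.0
        mixed = mixup_pseudo_label(src, tgt, 0.5)
        np.testing.assert_allclose(mixed[0, :, 0, 0], [0.5, 0.5])

    def test_out_of_range_lambda_raises(self, rng):
        p = random_prob_maps(rng)
        with pytest.raises(ValueError):
            mixup_pseudo_label(p, p, 1.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), lam=st.floats(0.0, 1.0))
    def test_mixup_output_is_valid_distribution(self, seed, lam):
        r = np.random.default_rng(seed)
        src = random_prob_maps(r, n=1, c=3, h=4, w=4)
        tgt = random_prob_maps(r, n=1, c=3, h=4, w=4)
        mixed = mixup_pseudo_label(src, tgt, lam)
        assert mixed.min() >= 0
        np.testing.assert_allclose(mixed.sum(axis=1), 1.0, atol=1e-9)


class TestKLDistillation:
    def test_identical_distributions_give_zero(self, rng):
        q = random_prob_maps(rng)
        assert kl_distillation_loss(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_class_value(self):
        q = np.zeros((1, 2, 1, 1))
        q[0, 0], q[0, 1] = 0.9, 0.1
        y = np.full((1, 2, 1, 1), 0.5)
        expected = 0.9 * math.log(0.9 / 0.5) + 0.1 * math.log(0.1 / 0.5)
        assert kl_distillation_loss(q, y) == pytest.approx(expected, rel=1e-9)

    def test_matches_explicit_loop_oracle(self, rng):
        q = random_prob_maps(rng, n=2, c=4, h=8, w=8)
        y = random_prob_maps(rng, n=2, c=4, h=8, w=8)
        assert kl_distillation_loss(q, y) == pytest.approx(loop_kl(q, y), abs=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        q = random_prob_maps(r, n=1, c=4, h=4, w=4)
        y = random_prob_maps(r, n=1, c=4, h=4, w=4)
        assert kl_distillation_loss(q, y) >= -1e-12


class TestEntropy:
    def test_one_hot_entropy_is_zero(self):
        label = np.array([[[0, 1], [2, 3]]])
        p = np.transpose(np.eye(4)[label], (0, 3, 1, 2))
        assert entropy_loss(p) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_entropy_is_log_c(self):
        p = np.full((1, 4, 4, 4), 0.25)
        assert entropy_loss(p) == pytest.approx(math.log(4), rel=1e-9)

    def test_matches_explicit_loop_oracle(self, rng):
        q = random_prob_maps(rng, n=2, c=4, h=8, w=8)
        assert entropy_loss(q) == pytest.approx(loop_entropy(q), abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_by_log_c(self, seed):
        r = np.random.default_rng(seed)
        q = random_prob_maps(r, n=1, c=4, h=4, w=4)
        assert -1e-12 <= entropy_loss(q) <= math.log(4) + 1e-12


class TestTotalLoss:
    def test_final_epoch_drops_entropy_term(self, rng):
        q = random_prob_maps(rng)
        y = random_prob_maps(rng)
        state = ScheduleState(iteration=10, total_epochs=10)
        tot, comps = total_loss(q, y, state)
        assert comps["alpha"] == 0.0
        assert tot == pytest.approx(comps["kl"], rel=1e-12)

    def test_initial_epoch_weights_are_one_and_five(self, rng):
        q = random_prob_maps(rng)
        y = random_prob_maps(rng)
        state = ScheduleState(iteration=0, total_epochs=10)
        tot, comps = total_loss(q, y, state)
        assert comps["alpha"] == 5.0
        assert comps["lambda"] == 1.0
        assert tot == pytest.approx(comps["kl"] + 5.0 * comps["entropy"], abs=1e-7)

    def test_total_equals_sum_of_components(self, rng):
        q = random_prob_maps(rng)
        y = random_prob_maps(rng)
        state = ScheduleState(iteration=3, total_epochs=10)
        tot, comps = total_loss(q, y, state)
        assert tot == pytest.approx(
            kl_distillation_loss(q, y) + comps["alpha"] * entropy_loss(q), abs=1e-7
        )


class TestGradientThroughMixup:
    def test_matches_finite_difference_of_mixture_kl(self, rng):
        """Disabling the pseudo-label stop-gradient yields the exact
        derivative of KL(q || lam*s + (1-lam)*q) w.r.t. q."""
        from bbuda.losses import kl_distillation_loss_through_mixup

        q = random_prob_maps(rng, n=1, c=3, h=2, w=2)
        s = random_prob_maps(rng, n=1, c=3, h=2, w=2)
        lam = 0.4
        _, grad = kl_distillation_loss_through_mixup(q, s, lam,
                                                     return_grad=True)

        def unconstrained(qq):
            # same functional form, q treated as free positive variables
            yy = lam * s + (1 - lam) * qq
            return float((qq * (np.log(qq) - np.log(yy))).sum()) / 4

        eps = 1e-7
        for k in range(3):
            up, down = q.copy(), q.copy()
            up[0, k, 1, 1] += eps
            down[0, k, 1, 1] -= eps
            num = (unconstrained(up) - unconstrained(down)) / (2 * eps)
            assert num == pytest.approx(grad[0, k, 1, 1], rel=1e-4, abs=1e-8)

    def test_reduces_to_stopgrad_value_at_lambda_one(self, rng):
        from bbuda.losses import kl_distillation_loss_through_mixup

        q = random_prob_maps(rng)
        s = random_prob_maps(rng)
        assert kl_distillation_loss_through_mixup(q, s, 1.0) == pytest.approx(
            kl_distillation_loss(q, s), abs=1e-9
        )


class TestEntropyMinimizationEffect:
    def test_gradient_descent_on_entropy_sharpens_predictions(self, rng):
        """Descending the entropy loss through a softmax strictly increases
        mean per-pixel confidence (max probability), barring a few steps."""
        from bbuda.engine.layers import Softmax

        logits = 0.5 * rng.standard_normal((1, 4, 8, 8))
        sm = Softmax()
        confidences = []
        for _ in range(50):
            p = sm.forward(logits)
            confidences.append(p.max(axis=1).mean())
            _, grad = entropy_loss(p, return_grad=True)
            dlogits = sm.backward(grad)
            logits = logits - 5.0 * dlogits
        diffs = np.diff(confidences)
        assert (diffs <= 0).sum() <= 5
        assert confidences[-1] > confidences[0]
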