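"""Loss terms against independent scalar-loop oracles, plus stop-gradient
and weighting contracts."""

import numpy as np
import pytest

import oracles
from conftest import random_probs
from dcclnet import autodiff as ad
from dcclnet import losses, metrics
from dcclnet.backbones import SegOutput
from dcclnet.losses import (ConfigError, aux_consistency_loss, ce_loss,
                            cotrain_loss, dice_loss, make_pseudo_label, mse,
                            one_hot, supervised_loss, teacher_consistency_loss,
                            total_loss)


def seg(probs):
    probs = ad.as_tensor(probs)
    return SegOutput(logits=ad.log(probs, eps=1e-12), probs=probs)


class TestDice:
    def test_perfect_overlap_near_zero(self, rng):
        target = one_hot(rng.integers(0, 3, (6, 6)), 3)
        assert dice_loss(target.astype(float), target).item() < 1e-4

    def test_uniform_probs_half_foreground_toy(self):
        # C=2 on a 4x4 map, half the pixels foreground, uniform 1/2 probs:
        # per-class Dice score 0.5, loss 0.5
        target = np.zeros((4, 4), dtype=int)
        target[:2] = 1
        probs = np.full((2, 4, 4), 0.5)
        val = dice_loss(probs, one_hot(target, 2)).item()
        assert abs(val - 0.5) < 1e-3
        assert abs(val - oracles.dice_loss_loop(probs, one_hot(target, 2))) < 1e-6

    def test_disjoint_hard_masks_approach_one(self):
        pred = one_hot(np.zeros((4, 4), dtype=int), 2).astype(float)
        target = one_hot(np.ones((4, 4), dtype=int), 2)
        assert dice_loss(pred, target).item() > 1 - 1e-3

    def test_matches_loop_oracle_on_random_tensors(self, rng):
        for _ in range(5):
            probs = random_probs(rng, (3, 2, 4))
            target = one_hot(rng.integers(0, 3, (2, 4)), 3)
            assert abs(dice_loss(probs, target).item()
                       - oracles.dice_loss_loop(probs, target)) < 1e-6

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((2, 4, 4)), np.zeros((2, 3, 3)))

    def test_hard_dice_complements_confusion_count_dsc(self, rng):
        """For one-hot predictions, per-class (1 - dice loss) equals the
        confusion-count DSC up to the smoothing epsilon."""
        pred_idx = rng.integers(0, 2, (8, 8))
        true_idx = rng.integers(0, 2, (8, 8))
        pred = one_hot(pred_idx, 2).astype(float)
        for c in range(2):
            per_class = 1.0 - dice_loss(pred[c:c + 1], one_hot(true_idx, 2)[c:c + 1]).item()
            counted = metrics.dsc(pred_idx == c, true_idx == c)
            assert abs(per_class - counted) < 1e-3


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        target = np.zeros((3, 3), dtype=int)
        probs = one_hot(target, 2).astype(float)
        assert ce_loss(probs, target).item() < 1e-9

    def test_uniform_probs_log4(self):
        probs = np.full((4, 5, 5), 0.25)
        target = np.random.default_rng(0).integers(0, 4, (5, 5))
        assert abs(ce_loss(probs, target).item() - np.log(4)) < 1e-9

    def test_joint_spatial_permutation_invariance(self, rng):
        probs = random_probs(rng, (3, 4, 4))
        target = rng.integers(0, 3, (4, 4))
        perm = rng.permutation(16)
        probs_p = probs.reshape(3, -1)[:, perm].reshape(3, 4, 4)
        target_p = target.reshape(-1)[perm].reshape(4, 4)
        assert abs(ce_loss(probs, target).item()
                   - ce_loss(probs_p, target_p).item()) < 1e-9

    def test_matches_loop_oracle(self, rng):
        probs = random_probs(rng, (2, 2, 3))
        target = rng.integers(0, 2, (2, 3))
        assert abs(ce_loss(probs, target).item()
                   - oracles.ce_loss_loop(probs, target)) < 1e-6

    def test_out_of_range_target_raises(self):
        with pytest.raises(IndexError):
            ce_loss(np.full((2, 2, 2), 0.5), np.full((2, 2), 5))


class TestSupervised:
    def test_equals_half_ce_plus_dice(self, rng):
        probs = random_probs(rng, (4, 8, 8))
        target = rng.integers(0, 4, (8, 8))
        combined = supervised_loss(seg(probs), target).item()
        parts = 0.5 * (ce_loss(probs, target).item()
                       + dice_loss(probs, one_hot(target, 4)).item())
        assert abs(combined - parts) < 1e-9

    def test_uniform_probs_oracle_value(self, rng):
        probs = np.full((4, 8, 8), 0.25)
        target = rng.integers(0, 4, (8, 8))
        expected = 0.5 * (oracles.ce_loss_loop(probs, target)
                          + oracles.dice_loss_loop(probs, one_hot(target, 4)))
        assert abs(supervised_loss(seg(probs), target).item() - expected) < 1e-6
        assert abs(oracles.ce_loss_loop(probs, target) - np.log(4)) < 1e-6


class TestAuxConsistency:
    def test_identical_outputs_zero(self, rng):
        main = seg(random_probs(rng, (2, 3, 3)))
        assert aux_consistency_loss(main, [main, main, main]).item() < 1e-12

    def test_constant_offset_closed_form(self):
        base = np.full((2, 2, 2), 0.5)
        c = 0.125
        main = seg(base)
        auxes = [seg(base + c), seg(base), seg(base)]
        val = aux_consistency_loss(main, auxes).item()
        assert abs(val - c ** 2 / 3) < 1e-9
        brute = sum(oracles.mse_loop(base, a.probs.data) for a in auxes) / 3
        assert abs(val - brute) < 1e-9

    def test_permutation_invariance(self, rng):
        main = seg(random_probs(rng, (2, 3, 3)))
        auxes = [seg(random_probs(rng, (2, 3, 3))) for _ in range(3)]
        a = aux_consistency_loss(main, auxes).item()
        b = aux_consistency_loss(main, auxes[::-1]).item()
        assert abs(a - b) < 1e-12

    def test_wrong_count_raises(self, rng):
        main = seg(random_probs(rng, (2, 3, 3)))
        with pytest.raises(ConfigError):
            aux_consistency_loss(main, [main])

    def test_gradient_reaches_main_and_aux(self, rng):
        main_p = ad.Tensor(random_probs(rng, (2, 3, 3)), requires_grad=True)
        aux_p = ad.Tensor(random_probs(rng, (2, 3, 3)), requires_grad=True)
        main = SegOutput(logits=main_p, probs=main_p)
        aux = SegOutput(logits=aux_p, probs=aux_p)
        aux_consistency_loss(main, [aux, aux, aux]).backward()
        assert main_p.grad is not None and np.abs(main_p.grad).sum() > 0
        assert aux_p.grad is not None and np.abs(aux_p.grad).sum() > 0


class TestTeacherConsistency:
    def test_identical_outputs_zero(self, rng):
        s = seg(random_probs(rng, (2, 4, 4)))
        assert teacher_consistency_loss(s, s).item() < 1e-12

    def test_constant_offset_is_c_squared(self):
        base = np.full((2, 2, 2), 0.4)
        c = 0.05
        val = teacher_consistency_loss(seg(base + c), seg(base)).item()
        assert abs(val - c ** 2) < 1e-12
        assert abs(val - oracles.mse_loop(base + c, base)) < 1e-12

    def test_teacher_receives_no_gradient(self, rng):
        sp = ad.Tensor(random_probs(rng, (2, 3, 3)), requires_grad=True)
        tp = ad.Tensor(random_probs(rng, (2, 3, 3)), requires_grad=True)
        loss = teacher_consistency_loss(SegOutput(logits=sp, probs=sp),
                                        SegOutput(logits=tp, probs=tp))
        loss.backward()
        assert sp.grad is not None
        assert tp.grad is None  # detached: no gradient path to the teacher


class TestPseudoLabels:
    def test_strict_argmax(self, rng):
        probs = random_probs(rng, (4, 6, 6))
        np.testing.assert_array_equal(
            make_pseudo_label(seg(probs)), oracles.argmax_onehot_loop(probs))

    def test_tie_breaks_to_lowest_class(self):
        probs = np.full((3, 2, 2), 1 / 3)
        pl = make_pseudo_label(seg(probs))
        np.testing.assert_array_equal(pl[0], 1.0)
        np.testing.assert_array_equal(pl[1:], 0.0)

    def test_idempotent_on_one_hot(self, rng):
        oh = one_hot(rng.integers(0, 3, (4, 4)), 3).astype(float)
        np.testing.assert_array_equal(make_pseudo_label(seg(oh)), oh)


class TestCotrain:
    def test_identical_hard_outputs_near_zero(self, rng):
        oh = one_hot(rng.integers(0, 2, (4, 4)), 2).astype(float)
        assert cotrain_loss(seg(oh), seg(oh)).item() < 1e-3

    def test_symmetric_under_argument_swap(self, rng):
        a, b = seg(random_probs(rng, (3, 4, 4))), seg(random_probs(rng, (3, 4, 4)))
        assert abs(cotrain_loss(a, b).item() - cotrain_loss(b, a).item()) < 1e-9

    def test_hand_counted_toy_case(self):
        # 2x2, C=2: u predicts classes [[0,0],[1,1]], su predicts [[0,1],[1,1]]
        u_idx = np.array([[0, 0], [1, 1]])
        su_idx = np.array([[0, 1], [1, 1]])
        u = seg(one_hot(u_idx, 2).astype(float))
        su = seg(one_hot(su_idx, 2).astype(float))
        val = cotrain_loss(u, su).item()
        brute = (oracles.dice_loss_loop(u.probs.data, one_hot(su_idx, 2))
                 + oracles.dice_loss_loop(su.probs.data, one_hot(u_idx, 2)))
        assert abs(val - brute) < 1e-9

    def test_pseudo_labels_are_detached_both_ways(self, rng):
        up = ad.Tensor(random_probs(rng, (2, 3, 3)), requires_grad=True)
        sp = ad.Tensor(random_probs(rng, (2, 3, 3)), requires_grad=True)
        loss = cotrain_loss(SegOutput(logits=up, probs=up),
                            SegOutput(logits=sp, probs=sp))
        loss.backward()
        # both sides get a *prediction* gradient but perturbing one side's
        # values does not move the other side's pseudo-label target
        assert up.grad is not None and sp.grad is not None
        # finite-difference: nudging su's probs slightly (without changing its
        # argmax) leaves u's gradient unchanged
        g_before = up.grad.copy()
        up.grad = sp.grad = None
        bumped = sp.data + 1e-4 * (np.random.default_rng(0).random(sp.shape) - 0.5)
        loss2 = cotrain_loss(SegOutput(logits=up, probs=up),
                             SegOutput(logits=ad.Tensor(bumped, requires_grad=True),
                                       probs=ad.Tensor(bumped, requires_grad=True)))
        loss2.backward()
        np.testing.assert_allclose(up.grad, g_before, atol=1e-12)


class TestTotal:
    def test_zero_weights_reduce_to_supervised(self):
        total, bd = total_loss(1.25, 0.75, 9.0, 9.0, 9.0, lambda1=0.0, lambda2=0.0)
        assert total == 2.0 and bd.total == 2.0

    def test_zero_unsup_parts_ignore_weights(self):
        t1, _ = total_loss(1.0, 1.0, 0.0, 0.0, 0.0, lambda1=0.003, lambda2=0.1)
        t2, _ = total_loss(1.0, 1.0, 0.0, 0.0, 0.0, lambda1=0.01, lambda2=0.15)
        assert t1 == t2 == 2.0

    def test_documented_arithmetic_example(self):
        total, bd = total_loss(1.0, 1.0, 0.5, 0.5, 2.0, lambda1=0.01, lambda2=0.15)
        assert abs(total - 2.31) < 1e-9
        recombined = (bd.sup_u + bd.sup_su + bd.lambda1 * (bd.unsup_aux
                      + bd.unsup_teacher) + bd.lambda2 * bd.unsup_cotrain)
        assert abs(bd.total - recombined) < 1e-6

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigError):
            total_loss(1.0, lambda1=-0.1, lambda2=0.0)

    def test_tensor_parts_stay_differentiable(self, rng):
        p = ad.Tensor(np.array(2.0), requires_grad=True)
        total, bd = total_loss(p, 0.0, p * 3.0, 0.0, 0.0, lambda1=0.01, lambda2=0.15)
        total.backward()
        assert abs(p.grad - (1.0 + 0.03)) < 1e-9
        assert abs(bd.total - (2.0 + 0.01 * 6.0)) < 1e-9


class TestGenericProperties:
    def test_all_losses_finite_and_nonnegative(self, rng):
        for _ in range(10):
            a, b = random_probs(rng, (3, 4, 4)), random_probs(rng, (3, 4, 4))
            target = rng.integers(0, 3, (4, 4))
            vals = [
                dice_loss(a, one_hot(target, 3)).item(),
                ce_loss(a, target).item(),
                supervised_loss(seg(a), target).item(),
                aux_consistency_loss(seg(a), [seg(b)] * 3).item(),
                teacher_consistency_loss(seg(a), seg(b)).item(),
                cotrain_loss(seg(a), seg(b)).item(),
            ]
            assert all(np.isfinite(v) and v >= 0 for v in vals)

    def test_mse_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((3, 2)))
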