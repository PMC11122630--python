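"""Trainer wiring: data routing, ablation toggles, determinism, optimizer
exclusions, checkpoint resume and overfitting smoke."""

import numpy as np
import pytest

from dcclnet import phantom
from dcclnet.trainer import (Components, ConfigError, RunConfig, Trainer,
                             augment_pair, next_batch, predict, seed_streams)


def tiny_config(**kw):
    defaults = dict(n_classes=4, batch_labeled=2, batch_unlabeled=2,
                    total_iters=50, eval_every=25, unet_depth=2,
                    unet_base_channels=4, swin_patch=4, swin_embed=8,
                    swin_heads=2, swin_window=2, swin_blocks=1,
                    ramp_every=1, seed=0)
    defaults.update(kw)
    return RunConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_data():
    return phantom.make_split(phantom.PhantomSpec(
        image_size=16, n_images=12, labeled_fraction=0.4, seed=3))


class TestBatching:
    def test_batch_composition(self, tiny_data):
        cfg = tiny_config()
        tr = Trainer(cfg, tiny_data)
        batch = next_batch(tiny_data, tr.cyc_l, tr.cyc_u, cfg, tr.rngs["augment"])
        assert batch.x_l.shape == (2, 1, 16, 16)
        assert batch.y_l.shape == (2, 16, 16)
        assert batch.x_u.shape == (2, 1, 16, 16)

    def test_augmentation_keeps_labels_aligned(self):
        rng = np.random.default_rng(0)
        img = np.arange(16.0).reshape(4, 4)
        lab = np.arange(16).reshape(4, 4)
        for _ in range(10):
            a_img, a_lab = augment_pair(img, lab, rng)
            np.testing.assert_array_equal(a_img.astype(int), a_lab)

    def test_labeled_and_unlabeled_cycle_independently(self, tiny_data):
        cfg = tiny_config(augment=False)
        tr1 = Trainer(cfg, tiny_data)
        # draw many labeled batches; the unlabeled stream must be unaffected
        for _ in range(5):
            tr1.cyc_l.take(cfg.batch_labeled)
        u_after = tr1.cyc_u.take(2)
        tr2 = Trainer(cfg, tiny_data)
        assert tr2.cyc_u.take(2) == u_after


class TestAblationContracts:
    def test_all_flags_off_zeroes_unsup_terms(self, tiny_data):
        cfg = tiny_config(components=Components(False, False, False))
        tr = Trainer(cfg, tiny_data)
        bd = tr.step()
        assert bd.unsup_aux == bd.unsup_teacher == bd.unsup_cotrain == 0.0
        assert bd.sup_su == 0.0
        assert bd.total == pytest.approx(bd.sup_u)

    def test_supervised_only_updates_only_unet(self, tiny_data):
        cfg = tiny_config(components=Components(False, False, False))
        tr = Trainer(cfg, tiny_data)
        assert tr.models.swin is None and tr.models.teacher is None
        assert tr.models.aux_decoders == []
        before = {n: p.data.copy() for n, p in tr.models.backbone().named_parameters()}
        tr.step()
        after = dict(tr.models.backbone().named_parameters())
        changed = [n for n in before if not np.array_equal(before[n], after[n].data)]
        assert changed  # the backbone itself moved

    def test_each_flag_activates_exactly_its_term(self, tiny_data):
        for flags, active in [
            (Components(True, False, False), "unsup_aux"),
            (Components(False, True, False), "unsup_teacher"),
            (Components(False, False, True), "unsup_cotrain"),
        ]:
            tr = Trainer(tiny_config(components=flags), tiny_data)
            bd = tr.step()
            for term in ("unsup_aux", "unsup_teacher", "unsup_cotrain"):
                if term == active:
                    assert getattr(bd, term) > 0.0, term
                else:
                    assert getattr(bd, term) == 0.0, term

    def test_loss_accounting_identity_every_iteration(self, tiny_data):
        tr = Trainer(tiny_config(total_iters=6), tiny_data)
        for _ in range(6):
            tr.step()
        for row in tr.log:
            recombined = (row["sup_u"] + row["sup_su"]
                          + row["lambda1"] * (row["unsup_aux"] + row["unsup_teacher"])
                          + row["lambda2"] * row["unsup_cotrain"])
            assert abs(row["total"] - recombined) < 1e-6


class TestOptimizerWiring:
    def test_teacher_excluded_from_optimizer(self, tiny_data):
        tr = Trainer(tiny_config(), tiny_data)
        opt_ids = {id(p) for p in tr.optimizer.params}
        teach_ids = {id(p) for p in tr.models.teacher.model.parameters()}
        assert not opt_ids & teach_ids
        assert teach_ids  # the teacher exists and has parameters

    def test_teacher_moves_only_by_ema(self, tiny_data):
        tr = Trainer(tiny_config(), tiny_data)
        t0 = {n: p.data.copy()
              for n, p in tr.models.teacher.model.named_parameters()}
        tr.step()
        # the teacher changed, but only towards the student
        s = dict(tr.models.backbone().named_parameters())
        lam = tr.models.teacher.decay
        for n, p in tr.models.teacher.model.named_parameters():
            # p_new should lie between old teacher and new student values
            expected = lam * t0[n] + (1 - lam) * s[n].data
            np.testing.assert_allclose(p.data, expected, atol=1e-6)

    def test_supervised_gradient_matches_ablated_model_at_zero_weights(self, tiny_data):
        """With ramp weights forced to 0, the full model's backbone update
        direction equals the supervised-only one."""
        cfg_full = tiny_config(ramp_base_weight=0.0, augment=False)
        cfg_sup = tiny_config(components=Components(False, False, False),
                              augment=False)
        tr_full, tr_sup = Trainer(cfg_full, tiny_data), Trainer(cfg_sup, tiny_data)
        tr_full.step(), tr_sup.step()
        a = dict(tr_full.models.backbone().named_parameters())
        b = dict(tr_sup.models.backbone().named_parameters())
        for n in a:
            np.testing.assert_allclose(a[n].data, b[n].data, atol=1e-6, err_msg=n)


class TestDeterminismAndResume:
    def test_identical_seeds_reproduce_loss_trajectory(self, tiny_data):
        log1 = [Trainer(tiny_config(), tiny_data).step().total for _ in [0]]
        tr_a, tr_b = Trainer(tiny_config(), tiny_data), Trainer(tiny_config(), tiny_data)
        rows_a = [tr_a.step().as_row() for _ in range(4)]
        rows_b = [tr_b.step().as_row() for _ in range(4)]
        assert rows_a == rows_b

    def test_resume_reproduces_original_trajectory(self, tiny_data, tmp_path):
        cfg = tiny_config(total_iters=20)
        base = Trainer(cfg, tiny_data)
        for _ in range(8):
            base.step()
        base.save_checkpoint(tmp_path / "mid.ckpt")
        tail_ref = [base.step().total for _ in range(8)]

        resumed = Trainer(cfg, tiny_data)
        resumed.load_checkpoint(tmp_path / "mid.ckpt")
        tail = [resumed.step().total for _ in range(8)]
        np.testing.assert_allclose(tail, tail_ref, rtol=1e-7)

    def test_empty_labeled_pool_rejected(self, tiny_data):
        import dataclasses

        empty = dataclasses.replace(tiny_data, labeled=[])
        with pytest.raises(ConfigError):
            Trainer(tiny_config(), empty)


class TestRunAndPredict:
    def test_short_run_produces_complete_log_and_best(self, tiny_data):
        cfg = tiny_config(total_iters=30, eval_every=10)
        run = Trainer(cfg, tiny_data).run()
        assert len(run.log) == 30
        assert [r["iteration"] for r in run.log] == list(range(30))
        assert len(run.val_history) == 3
        # selection maximises: best >= the first evaluation
        assert run.best_val_dsc >= run.val_history[0][1]
        assert run.test_report.n_items == len(tiny_data.test)

    def test_predict_is_deterministic_and_tie_breaks_low(self, tiny_data):
        cfg = tiny_config(total_iters=2, eval_every=2)
        run = Trainer(cfg, tiny_data).run()
        net = run.best_backbone()
        imgs = np.stack([p[0] for p in tiny_data.test[:2]])
        a, b = predict(net, imgs), predict(net, imgs)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (2, 16, 16)
        # uniform probabilities argmax to class 0
        net.decoder.head.weight.data[:] = 0.0
        net.decoder.head.bias.data[:] = 0.0
        np.testing.assert_array_equal(predict(net, imgs), 0)

    def test_overfit_smoke_reaches_high_dice_on_train_labels(self):
        """A supervised-only run on 4 images should overfit them."""
        data = phantom.make_split(phantom.PhantomSpec(
            image_size=16, n_images=10, labeled_fraction=1.0, seed=5))
        data.labeled = data.labeled[:4]
        cfg = tiny_config(components=Components(False, False, False),
                          total_iters=300, eval_every=100, batch_labeled=4,
                          unet_base_channels=8, unet_depth=3)
        run = Trainer(cfg, data).run()
        from dcclnet.trainer import evaluate_pairs

        rep = evaluate_pairs(run.best_backbone(), data.labeled, 4)
        assert rep.mean["dsc"] > 0.85
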