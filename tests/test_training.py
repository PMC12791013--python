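"""Losses, scheduler, checkpoint selection and a training smoke test."""

import math

import numpy as np
import pytest

from skelimpute.errors import ConfigError, EmptyInputError
from skelimpute.gaps import GapStats
from skelimpute.io import Sample
from skelimpute.nn.autodiff import Tensor
from skelimpute.nn.models import ModelConfig, build_model
from skelimpute.training import (TrainConfig, gaussian_nll_loss,
                                 masked_l1_loss, scheduled_lr, train)


def _mask(L=6, K=3, cells=((1, 0), (2, 2))):
    m = np.zeros((L, K), bool)
    for t, k in cells:
        m[t, k] = True
    return m


class TestMaskedL1:
    def test_zero_when_prediction_matches_target_on_gap(self, rng):
        t = rng.normal(size=(6, 3, 3))
        p = t + 10.0
        m = _mask()
        p[m] = t[m]
        assert masked_l1_loss(p, t, m) == 0.0

    def test_single_point_off_by_ones(self):
        t = np.zeros((4, 2, 3))
        p = np.zeros((4, 2, 3))
        m = np.zeros((4, 2), bool)
        m[1, 1] = True
        p[1, 1] = [1.0, 1.0, 1.0]
        assert masked_l1_loss(p, t, m) == pytest.approx(1.0)

    def test_matches_explicit_loop(self, rng):
        p = rng.normal(size=(8, 4, 2))
        t = rng.normal(size=(8, 4, 2))
        m = rng.random((8, 4)) < 0.4
        if not m.any():
            m[0, 0] = True
        acc = [abs(p[i, k, d] - t[i, k, d])
               for i in range(8) for k in range(4) if m[i, k]
               for d in range(2)]
        assert masked_l1_loss(p, t, m) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_empty_mask_raises(self, rng):
        t = rng.normal(size=(4, 2, 2))
        with pytest.raises(EmptyInputError):
            masked_l1_loss(t, t, np.zeros((4, 2), bool))

    def test_unmasked_target_perturbation_never_changes_loss(self, rng):
        p = rng.normal(size=(6, 3, 3))
        t = rng.normal(size=(6, 3, 3))
        m = _mask()
        base = masked_l1_loss(p, t, m)
        t2 = t.copy()
        t2[~m] += rng.normal(size=t2[~m].shape)
        assert masked_l1_loss(p, t2, m) == base


class TestGaussianNLL:
    def test_perfect_mean_unit_std_closed_form(self):
        t = np.zeros((4, 2, 3))
        s = np.ones_like(t)
        m = _mask(4, 2, [(0, 0), (3, 1)])
        expected = 0.5 * math.log(2 * math.pi)
        assert gaussian_nll_loss(t, s, t, m) == pytest.approx(expected)

    def test_minimized_at_std_equal_residual(self):
        t = np.zeros((3, 2, 1))
        p = t.copy()
        m = np.zeros((3, 2), bool)
        m[0, 0] = True
        p[0, 0] = 0.7  # residual 0.7
        def nll(sigma):
            s = np.full_like(t, sigma)
            return gaussian_nll_loss(p, s, t, m)
        best = 0.7
        eps = 1e-4
        assert nll(best) < nll(best + eps) and nll(best) < nll(best - eps)
        # derivative approximately zero at sigma = |residual|
        assert abs(nll(best + eps) - nll(best - eps)) / (2 * eps) < 1e-3

    def test_doubling_std_with_zero_residual_adds_log_two(self):
        t = np.zeros((3, 2, 2))
        m = _mask(3, 2, [(1, 1)])
        l1 = gaussian_nll_loss(t, np.ones_like(t), t, m)
        l2 = gaussian_nll_loss(t, 2 * np.ones_like(t), t, m)
        assert l2 - l1 == pytest.approx(math.log(2))

    def test_nonpositive_std_raises(self):
        t = np.zeros((3, 2, 2))
        m = _mask(3, 2, [(1, 1)])
        with pytest.raises(ConfigError):
            gaussian_nll_loss(t, np.zeros_like(t), t, m)

    def test_tensor_and_array_paths_agree(self, rng):
        p = rng.normal(size=(5, 3, 2))
        t = rng.normal(size=(5, 3, 2))
        s = np.exp(rng.normal(size=(5, 3, 2)))
        m = rng.random((5, 3)) < 0.5
        m[0, 0] = True
        a = gaussian_nll_loss(p, s, t, m)
        b = float(gaussian_nll_loss(Tensor(p), Tensor(s), t, m).data)
        assert a == pytest.approx(b, rel=1e-6)

    def test_loss_gradient_flows_only_through_masked_cells(self, rng):
        p = Tensor(rng.normal(size=(5, 3, 2)), requires_grad=True)
        t = rng.normal(size=(5, 3, 2))
        m = np.zeros((5, 3), bool)
        m[2, 1] = True
        loss = masked_l1_loss(p, t, m)
        loss.backward()
        grad_mask = np.repeat(m[..., None], 2, axis=-1)
        assert (p.grad[~grad_mask] == 0).all()
        assert (p.grad[grad_mask] != 0).all()


def test_scheduled_lr_formula():
    for e in (0, 1, 499, 500, 999, 1000, 1499):
        assert scheduled_lr(1e-3, e, 0.95, 500) == pytest.approx(
            1e-3 * 0.95 ** (e // 500))


def _constant_velocity_samples(rng, n, L=20, K=3, D=2):
    """A rigid body translating at constant velocity, min-max normalized."""
    from skelimpute.preprocess import minmax_normalize
    out = []
    for _ in range(n):
        offs = rng.uniform(-0.3, 0.3, size=(K, D))
        start = rng.uniform(-0.5, 0.5, size=(1, D))
        vel = rng.uniform(-0.03, 0.03, size=(1, D))
        coords = start[None] + offs[None] + vel[None] * np.arange(L)[:, None, None]
        out.append(minmax_normalize(
            Sample("c", 0, coords, np.zeros((L, K), bool)))[0])
    return out


_SMOKE_CFG = dict(epochs=200, lr=1e-2, batch_size=8, seed=0,
                  switch_prob=0.0, n_missing=1,
                  scheduler_gamma=0.5, scheduler_step=80)
_SMOKE_MAXGAP = 5


@pytest.fixture(scope="module")
def smoke_run():
    rng = np.random.default_rng(0)
    samples = _constant_velocity_samples(rng, 24)
    cfg = TrainConfig(**_SMOKE_CFG)
    model = build_model(ModelConfig(backbone="gru", K=3, D=2, L=20,
                                    n_layers=1, hidden=32), seed=0)
    stats = GapStats.uniform(3, max_length=_SMOKE_MAXGAP)
    model, history = train(model, samples[:16], samples[16:], cfg, stats)
    return model, history, cfg


class TestTrainLoop:
    def test_loss_decreases_by_an_order_of_magnitude(self, smoke_run):
        _, history, _ = smoke_run
        assert history.train_loss[-1] < 0.1 * history.train_loss[0]

    def test_best_epoch_is_argmin_of_validation_rmse(self, smoke_run):
        _, history, _ = smoke_run
        assert history.best_epoch == int(np.argmin(history.val_rmse))

    def test_history_lr_follows_schedule(self, smoke_run):
        _, history, cfg = smoke_run
        for e, lr in enumerate(history.lr):
            assert lr == pytest.approx(
                scheduled_lr(cfg.lr, e, cfg.scheduler_gamma, cfg.scheduler_step))

    def test_returned_model_attains_best_validation_rmse(self, smoke_run):
        from skelimpute.training import _stack_masked, _val_rmse, make_masked_batch
        model, history, cfg = smoke_run
        rng = np.random.default_rng(0)
        samples = _constant_velocity_samples(rng, 24)
        val_rng = np.random.default_rng(cfg.seed + 1)
        stats = GapStats.uniform(3, max_length=_SMOKE_MAXGAP)
        masked = make_masked_batch(samples[16:], stats, cfg.n_missing, 0.0,
                                   val_rng)
        vi, vm, vt = _stack_masked(masked)
        rmse = _val_rmse(model, vi, vm, vt, cfg.batch_size)
        assert rmse == pytest.approx(min(history.val_rmse), abs=1e-9)

    def test_same_seed_reproduces_history(self):
        rng = np.random.default_rng(0)
        samples = _constant_velocity_samples(rng, 12)
        stats = GapStats.uniform(3, max_length=18)
        hists = []
        for _ in range(2):
            cfg = TrainConfig(epochs=3, lr=1e-3, batch_size=4, seed=7,
                              switch_prob=0.1, n_missing=1)
            model = build_model(ModelConfig(backbone="gru", K=3, D=2, L=20,
                                            n_layers=1, hidden=8), seed=7)
            _, h = train(model, samples[:8], samples[8:], cfg, stats)
            hists.append(h)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_rmse == hists[1].val_rmse

    def test_incomplete_samples_rejected(self, rng):
        samples = _constant_velocity_samples(rng, 4)
        samples[0].missing[3, 1] = True
        cfg = TrainConfig(epochs=1, seed=0)
        model = build_model(ModelConfig(backbone="gru", K=3, D=2, L=20,
                                        n_layers=1, hidden=8), seed=0)
        with pytest.raises(ConfigError):
            train(model, samples[:2], samples[2:], cfg,
                  GapStats.uniform(3, 18))
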