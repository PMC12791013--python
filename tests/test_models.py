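"""Backbone contracts: shapes, determinism, embeddings, latents, checkpoints."""

import numpy as np
import pytest

from skelimpute.errors import ConfigError, ShapeError
from skelimpute.gaps import GapSpec, apply_gaps
from skelimpute.nn.autodiff import Tensor
from skelimpute.nn.models import (ModelConfig, build_model, extract_latent,
                                  load_checkpoint, predict, save_checkpoint)

BACKBONES = ["transformer", "gru", "tcn"]


def tiny_config(backbone, proba=False):
    sizes = {"transformer": dict(model_dim=16, n_layers=1, n_heads=2, ff_dim=16),
             "gru": dict(n_layers=1, hidden=12),
             "tcn": dict(n_layers=2, hidden=12)}
    return ModelConfig(backbone=backbone, proba=proba, K=4, D=3, L=20,
                       **sizes[backbone])


def batch(rng, B=3, L=20, K=4, D=3):
    inputs = rng.normal(size=(B, L, K, D))
    mask = rng.random((B, L, K)) < 0.15
    inputs[mask[..., None].repeat(D, -1)] = 0.0
    return inputs, mask


class TestForwardContract:
    @pytest.mark.parametrize("backbone", BACKBONES)
    def test_zero_input_gives_finite_output_of_right_shape(self, backbone):
        m = build_model(tiny_config(backbone), seed=0)
        mean, std = m(np.zeros((2, 20, 4, 3)), np.zeros((2, 20, 4), bool))
        assert mean.data.shape == (2, 20, 4, 3)
        assert np.isfinite(mean.data).all()
        assert std is None

    @pytest.mark.parametrize("backbone", BACKBONES)
    def test_proba_std_strictly_positive(self, backbone, rng):
        m = build_model(tiny_config(backbone, proba=True), seed=0)
        inputs, mask = batch(rng)
        mean, std = m(inputs, mask)
        assert std.data.shape == mean.data.shape
        assert (std.data > 0).all()

    @pytest.mark.parametrize("backbone", BACKBONES)
    def test_batch_independence_in_eval_mode(self, backbone, rng):
        m = build_model(tiny_config(backbone), seed=0).eval()
        inputs, mask = batch(rng, B=4)
        joint, _ = m(inputs, mask)
        solo, _ = m(inputs[1:2], mask[1:2])
        assert np.allclose(joint.data[1], solo.data[0], atol=1e-5)

    @pytest.mark.parametrize("backbone", BACKBONES)
    def test_deterministic_given_parameters(self, backbone, rng):
        m = build_model(tiny_config(backbone), seed=0).eval()
        inputs, mask = batch(rng)
        a, _ = m(inputs, mask)
        b, _ = m(inputs, mask)
        assert np.array_equal(a.data, b.data)

    def test_shape_mismatch_raises(self, rng):
        m = build_model(tiny_config("gru"), seed=0)
        with pytest.raises(ShapeError):
            m(np.zeros((1, 20, 5, 3)), np.zeros((1, 20, 5), bool))


def test_reference_transformer_parameter_count_stable_across_seeds():
    cfg = ModelConfig(backbone="transformer", K=8, D=3, L=60)
    n = [sum(p.data.size for p in build_model(cfg, seed=s).parameters())
         for s in (0, 1)]
    assert n[0] == n[1] == 408_579


class TestKeypointIdentity:
    def test_permuting_channels_alone_changes_output(self, rng):
        m = build_model(tiny_config("transformer"), seed=0).eval()
        inputs, mask = batch(rng, B=1)
        perm = np.array([2, 0, 3, 1])
        base, _ = m(inputs, mask)
        permuted, _ = m(inputs[:, :, perm], mask[:, :, perm])
        assert not np.allclose(permuted.data, base.data[:, :, perm], atol=1e-4)

    def test_permuting_channels_and_identities_permutes_output(self, rng):
        m = build_model(tiny_config("transformer"), seed=0).eval()
        inputs, mask = batch(rng, B=1)
        base, _ = m(inputs, mask)
        perm = np.array([2, 0, 3, 1])
        m.kp_emb.weight = Tensor(m.kp_emb.weight.data[perm],
                                 requires_grad=True)
        permuted, _ = m(inputs[:, :, perm], mask[:, :, perm])
        assert np.allclose(permuted.data, base.data[:, :, perm], atol=1e-5)


def test_gru_output_depends_on_future_frames(rng):
    # bidirectional recurrence: perturbing a later frame changes earlier output
    m = build_model(tiny_config("gru"), seed=0).eval()
    inputs, mask = batch(rng, B=1)
    base, _ = m(inputs, mask)
    pert = inputs.copy()
    pert[0, 15] += 5.0
    out, _ = m(pert, mask)
    assert not np.allclose(out.data[0, :10], base.data[0, :10], atol=1e-6)


def test_tcn_output_is_causal(rng):
    m = build_model(tiny_config("tcn"), seed=0).eval()
    inputs, mask = batch(rng, B=1)
    base, _ = m(inputs, mask)
    pert = inputs.copy()
    pert[0, 15] += 5.0
    out, _ = m(pert, mask)
    assert np.allclose(out.data[0, :15], base.data[0, :15], atol=1e-6)
    assert not np.allclose(out.data[0, 15:], base.data[0, 15:], atol=1e-6)


class TestLatent:
    def _masked(self, rng, start=5):
        coords = rng.normal(size=(20, 4, 3))
        from skelimpute.io import Sample
        s = Sample("r", 0, coords, np.zeros((20, 4), bool))
        return apply_gaps(s, [GapSpec(1, start, 6)])

    @pytest.mark.parametrize("backbone", ["transformer", "gru"])
    def test_latent_deterministic_and_fixed_length(self, backbone, rng):
        m = build_model(tiny_config(backbone), seed=0)
        masked = self._masked(rng)
        v1 = extract_latent(m, masked)
        v2 = extract_latent(m, masked)
        assert np.array_equal(v1, v2)
        other = extract_latent(m, self._masked(rng, start=11))
        assert other.shape == v1.shape

    def test_tcn_latent_unsupported(self, rng):
        m = build_model(tiny_config("tcn"), seed=0)
        with pytest.raises(ConfigError):
            extract_latent(m, self._masked(rng))


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, tmp_path, rng):
        m = build_model(tiny_config("transformer", proba=True), seed=3)
        inputs, mask = batch(rng)
        ref, ref_std = m.eval()(inputs, mask)
        save_checkpoint(m, tmp_path / "ck.npz", extra={"note": 1})
        m2, extra = load_checkpoint(tmp_path / "ck.npz")
        assert extra == {"note": 1}
        out, out_std = m2.eval()(inputs, mask)
        assert np.array_equal(out.data, ref.data)
        assert np.array_equal(out_std.data, ref_std.data)


def test_trained_model_beats_untrained_on_held_out_gaps(desk_data, trained_gru):
    from skelimpute.pipeline import evaluate_model_on_cases, make_eval_cases
    model, _ = trained_gru
    untrained = build_model(model.config, seed=123)
    cases = make_eval_cases(desk_data, seed=5, n_cases=40)
    trained_rmse = evaluate_model_on_cases(model, cases)["rmse"]
    untrained_rmse = evaluate_model_on_cases(untrained, cases)["rmse"]
    assert trained_rmse < untrained_rmse


def test_predict_wraps_single_sample(rng, desk_data, trained_gru):
    model, _ = trained_gru
    from skelimpute.pipeline import make_eval_cases
    case = make_eval_cases(desk_data, seed=6, n_cases=1)[0]
    pred = predict(model, case.masked)
    assert pred.mean.shape == case.normalized.coords.shape
    assert pred.std is None
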