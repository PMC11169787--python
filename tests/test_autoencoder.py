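from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from spalp.autoencoder import (
    AEConfig,
    AEModel,
    encode,
    kl_bernoulli,
    loss_and_grads,
    reconstruction_loss,
    sparsity_penalty,
    train_autoencoder,
)

from .oracles import finite_difference_grads


def _toy_model(input_dim=2, latent=2, seed=0, **cfg):
    config = AEConfig(latent_dim=latent, seed=seed, **cfg)
    rng = np.random.default_rng(seed)
    return AEModel(
        w_enc=rng.normal(size=(input_dim, latent)),
        b_enc=rng.normal(size=latent),
        w_dec=rng.normal(size=(latent, input_dim)),
        b_dec=rng.normal(size=input_dim),
        config=config,
    )


class TestReconstructionLoss:
    def test_identity_map_zero(self):
        # saturate the decoder so y == x for x in {0,1}
        model = _toy_model()
        model.w_enc[:] = 0.0
        model.b_enc[:] = 0.0
        model.w_dec[:] = 0.0
        x = np.array([[0.5, 0.5]])
        model.b_dec[:] = 0.0  # sigmoid(0) = 0.5 reproduces x exactly
        assert reconstruction_loss(model, x) == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic_quarter(self):
        # y(x) = (0.5, 0.5) against x = (1, 0): 0.5*(0.25 + 0.25) = 0.25
        model = _toy_model()
        model.w_dec[:] = 0.0
        model.b_dec[:] = 0.0
        x = np.array([[1.0, 0.0]])
        assert reconstruction_loss(model, x) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_non_negative(self, seed):
        model = _toy_model(input_dim=4, latent=3, seed=seed)
        x = np.random.default_rng(seed).random((6, 4))
        assert reconstruction_loss(model, x) >= 0.0

    def test_non_finite_input_rejected(self):
        model = _toy_model()
        with pytest.raises(ValueError, match="finite"):
            reconstruction_loss(model, np.array([[np.nan, 0.0]]))


class TestSparsityPenalty:
    def test_kl_zero_at_target(self):
        assert kl_bernoulli(0.05, np.array([0.05])).sum() == pytest.approx(0.0)

    def test_kl_worked_value(self):
        # rho=0.05, rho_hat=0.5: 0.05*ln(0.1) + 0.95*ln(0.95/0.5)
        expected = 0.05 * math.log(0.1) + 0.95 * math.log(0.95 / 0.5)
        assert kl_bernoulli(0.05, np.array([0.5]))[0] == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.4946, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_gibbs_inequality(self, seed):
        rng = np.random.default_rng(seed)
        rho_hat = rng.uniform(0.01, 0.99, size=5)
        vals = kl_bernoulli(0.05, rho_hat)
        assert (vals >= 0.0).all()
        assert vals[np.abs(rho_hat - 0.05) > 1e-6].min() > 0.0

    def test_penalty_via_model(self):
        model = _toy_model(rho=0.05)
        x = np.random.default_rng(0).random((8, 2))
        h = encode(model, x)
        expected = kl_bernoulli(0.05, h.mean(axis=0)).sum()
        assert sparsity_penalty(model, x) == pytest.approx(expected, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("beta", [0.0, 1.0, 3.0])
    def test_analytic_matches_finite_differences(self, beta):
        # 5 samples x 4 features x 3 hidden units
        config = AEConfig(latent_dim=3, rho=0.05, beta=beta, seed=1)
        rng = np.random.default_rng(1)
        model = AEModel(
            w_enc=rng.normal(scale=0.5, size=(4, 3)),
            b_enc=rng.normal(scale=0.1, size=3),
            w_dec=rng.normal(scale=0.5, size=(3, 4)),
            b_dec=rng.normal(scale=0.1, size=4),
            config=config,
        )
        x = rng.random((5, 4))
        *_, grads = loss_and_grads(model, x)
        params = [model.w_enc, model.b_enc, model.w_dec, model.b_dec]

        def total():
            return reconstruction_loss(model, x) + beta * sparsity_penalty(model, x)

        fd = finite_difference_grads(total, params)
        for g, g_fd in zip(grads, fd):
            denom = np.maximum(np.abs(g_fd), 1e-8)
            assert np.max(np.abs(g - g_fd) / denom) < 1e-4

    def test_beta_zero_excludes_sparsity_from_gradient(self):
        config0 = AEConfig(latent_dim=3, beta=0.0, seed=2)
        rng = np.random.default_rng(2)
        arrays = dict(
            w_enc=rng.normal(size=(4, 3)),
            b_enc=rng.normal(size=3),
            w_dec=rng.normal(size=(3, 4)),
            b_dec=rng.normal(size=4),
        )
        x = rng.random((5, 4))
        model = AEModel(**{k: v.copy() for k, v in arrays.items()}, config=config0)
        *_, grads = loss_and_grads(model, x)

        def recon_only():
            return reconstruction_loss(model, x)

        fd = finite_difference_grads(
            recon_only, [model.w_enc, model.b_enc, model.w_dec, model.b_dec]
        )
        for g, g_fd in zip(grads, fd):
            assert np.allclose(g, g_fd, atol=1e-7)


@pytest.fixture(scope="module")
def fixture_matrix():
    rng = np.random.default_rng(7)
    return (rng.random((200, 100)) < 0.05).astype(float)


class TestTraining:

    def test_loss_decreases(self, fixture_matrix):
        config = AEConfig(latent_dim=16, epochs=100, seed=0)
        _, trace = train_autoencoder(fixture_matrix, config)
        assert trace.total[-1] < trace.total[0]

    def test_smoothed_trace_non_increasing(self, fixture_matrix):
        config = AEConfig(latent_dim=16, epochs=100, seed=0)
        _, trace = train_autoencoder(fixture_matrix, config)
        smoothed = np.convolve(trace.total, np.ones(10) / 10, mode="valid")
        assert (np.diff(smoothed) <= 1e-6).all()

    def test_determinism(self, fixture_matrix):
        config = AEConfig(latent_dim=8, epochs=20, seed=5)
        _, t1 = train_autoencoder(fixture_matrix, config)
        _, t2 = train_autoencoder(fixture_matrix, config)
        assert t1.total == t2.total
        assert t1.reconstruction == t2.reconstruction

    def test_large_beta_pulls_activation_toward_rho(self, fixture_matrix):
        config = AEConfig(latent_dim=16, rho=0.05, beta=10.0, epochs=150, seed=3)
        rng = np.random.default_rng(config.seed)
        from spalp.autoencoder import _init_model

        init = _init_model(fixture_matrix.shape[1], config, rng)
        gap_before = abs(encode(init, fixture_matrix).mean() - config.rho)
        model, _ = train_autoencoder(fixture_matrix, config)
        gap_after = abs(encode(model, fixture_matrix).mean() - config.rho)
        assert gap_after < gap_before

    def test_minibatch_mode_runs(self, fixture_matrix):
        config = AEConfig(latent_dim=8, epochs=5, batch_size=64, seed=0)
        _, trace = train_autoencoder(fixture_matrix, config)
        assert len(trace.total) == 5

    def test_trace_finite_and_nonnegative(self, fixture_matrix):
        config = AEConfig(latent_dim=8, epochs=10, seed=1)
        _, trace = train_autoencoder(fixture_matrix, config)
        arr = np.array([trace.reconstruction, trace.sparsity, trace.total])
        assert np.isfinite(arr).all() and (arr >= 0).all()


class TestEncode:
    def test_hmdd_shaped_dimensions(self):
        rng = np.random.default_rng(0)
        x_m = (rng.random((495, 383)) < 0.03).astype(float)
        config = AEConfig(latent_dim=128, epochs=1, seed=0)
        model, _ = train_autoencoder(x_m, config)
        assert encode(model, x_m).shape == (495, 128)
        x_d = x_m.T.copy()
        model_d, _ = train_autoencoder(x_d, replace(config, seed=1))
        assert encode(model_d, x_d).shape == (383, 128)

    def test_output_in_open_unit_interval(self):
        model = _toy_model(input_dim=4, latent=3)
        h = encode(model, np.random.default_rng(0).random((10, 4)))
        assert (h > 0).all() and (h < 1).all()

    def test_shape_mismatch_rejected(self):
        model = _toy_model(input_dim=4, latent=3)
        with pytest.raises(ValueError, match="columns"):
            encode(model, np.zeros((2, 5)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho": 0.0},
            {"rho": 1.0},
            {"latent_dim": 0},
            {"beta": -1.0},
            {"learning_rate": 0.0},
            {"epochs": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AEConfig(**kwargs)
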