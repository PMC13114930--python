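"""VMIB model: gradients, objective arithmetic, training contracts, bounds."""

import numpy as np
import pytest

from mmib._nn import softmax_nll
from mmib.synthgen import LatentClassGenConfig, ModalitySpec, gen_latent_class
from mmib.vmib import (
    VMIBConfig,
    _build_model,
    evaluate_model,
    gaussian_kl_standard,
    information_plane_sweep,
    loss_and_grads,
    probe_retention,
    representation_entropy,
    train_vmib,
)


@pytest.fixture(scope="module")
def tiny_data():
    return gen_latent_class(
        LatentClassGenConfig(
            n=120,
            n_classes=3,
            latent_dim=4,
            seed=0,
            modalities=[
                ModalitySpec("a", 3, 1.0, [0, 1]),
                ModalitySpec("b", 2, 0.5, [2]),
            ],
        )
    )


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_data):
        """Hand-derived gradients (incl. consistency penalty) vs central differences."""
        cfg = VMIBConfig(
            latent_dim=3, hidden_units=5, predictor_hidden=4,
            dropout_rate=0.0, seed=1, epochs=1,
        )
        model = _build_model(tiny_data, cfg)
        jitter = np.random.default_rng(5)
        for k in model.params:  # move off the ReLU kink at exact zero
            model.params[k] = model.params[k] + 0.05 * jitter.standard_normal(
                model.params[k].shape
            )
        blocks = model.standardize({k: v[:8] for k, v in tiny_data.modalities.items()})
        y = tiny_data.labels[:8]
        eps = np.random.default_rng(0).standard_normal((8, 3))
        kw = dict(lam=0.1, eps=eps, gamma_t=0.05, subsets=[["a"], ["b"]])
        _, grads = loss_and_grads(model, blocks, y, **kw)

        def loss():
            return loss_and_grads(model, blocks, y, **kw)[0]["loss"]

        checked = 0
        for k, g in grads.items():
            flat = model.params[k].ravel()
            gflat = np.asarray(g).ravel()
            for j in range(0, flat.size, max(1, flat.size // 4)):
                h, old = 1e-6, flat[j]
                flat[j] = old + h
                lp = loss()
                flat[j] = old - h
                lm = loss()
                flat[j] = old
                assert (lp - lm) / (2 * h) == pytest.approx(gflat[j], abs=1e-6)
                checked += 1
        assert checked > 20


class TestObjectiveArithmetic:
    def test_lambda_zero_loss_is_pure_nll(self, tiny_data):
        cfg = VMIBConfig(latent_dim=3, hidden_units=5, dropout_rate=0.0, seed=1)
        model = _build_model(tiny_data, cfg)
        blocks = model.standardize(tiny_data.modalities)
        eps = np.zeros((tiny_data.n_samples, 3))
        comps, _ = loss_and_grads(model, blocks, tiny_data.labels, lam=0.0, eps=eps)
        assert comps["loss"] == comps["nll"]

    def test_posterior_equal_prior_zero_kl(self):
        mu = np.zeros((7, 4))
        assert gaussian_kl_standard(mu, np.zeros_like(mu)) == 0.0

    def test_single_sample_closed_form(self):
        """-ln 0.8 + 0.1 * KL(N(1,1)||N(0,1)) = -ln 0.8 + 0.1*0.5."""
        logits = np.log(np.array([[0.8, 0.2]]))
        nll, _ = softmax_nll(logits, np.array([0]))
        kl = gaussian_kl_standard(np.array([[1.0]]), np.array([[0.0]]))
        assert nll + 0.1 * kl == pytest.approx(-np.log(0.8) + 0.05, abs=1e-12)

    def test_reparameterization_collapses_at_zero_variance(self, tiny_data):
        """With variance -> 0, stochastic and deterministic passes agree."""
        cfg = VMIBConfig(latent_dim=3, hidden_units=5, dropout_rate=0.0, seed=1)
        model = _build_model(tiny_data, cfg)
        blocks = model.standardize(tiny_data.modalities)
        mu, logvar, _ = model.encode(blocks, train=False)
        eps = np.random.default_rng(3).standard_normal(mu.shape)
        z_stoch = mu + np.exp(0.5 * np.full_like(logvar, -60.0)) * eps
        assert np.allclose(z_stoch, mu, atol=1e-10)


class TestTraining:
    def test_separable_data_high_accuracy(self, latent_data, small_vmib_config, latent_model):
        ev = evaluate_model(latent_model, latent_data)
        assert ev["accuracy"] >= 0.8
        assert ev["auc"] >= 0.95

    def test_deterministic_given_seed(self, tiny_data):
        cfg = VMIBConfig(
            latent_dim=4, hidden_units=8, epochs=5, seed=11, dropout_rate=0.2
        )
        m1, m2 = train_vmib(tiny_data, cfg), train_vmib(tiny_data, cfg)
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)
        assert m1.history == m2.history

    def test_history_records_loss_components(self, latent_model, small_vmib_config):
        assert len(latent_model.history) == small_vmib_config.epochs
        assert {"nll", "kl", "lr"} <= set(latent_model.history[0])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            VMIBConfig(lambda_compress=-0.1)
        with pytest.raises(ValueError):
            VMIBConfig(epochs=0)


@pytest.fixture(scope="module")
def sweep(latent_data):
    cfg = VMIBConfig(
        latent_dim=16, hidden_units=64, epochs=80, dropout_rate=0.1, seed=3
    )
    return information_plane_sweep(latent_data, cfg, [1e-4, 1e-3, 1e-2, 1e-1, 1.0])


class TestInformationPlane:
    def test_sorted_by_lambda_with_logged_seeds(self, sweep):
        lams = [p.lam for p in sweep]
        assert lams == sorted(lams)
        assert len({p.seed for p in sweep}) == len(sweep)

    def test_compression_bound_nonnegative(self, sweep):
        assert all(p.compression_bound >= 0 for p in sweep)

    def test_compression_shrinks_with_lambda(self, sweep):
        comp = [p.compression_bound for p in sweep]
        for lo, hi in zip(comp[1:], comp[:-1]):
            assert lo <= hi * 1.05  # up to 5% optimization noise
        assert comp[-1] < comp[0]

    def test_prediction_bound_below_label_entropy(self, sweep, latent_data):
        from mmib.infocore import empirical_label_distribution, entropy_categorical

        h_y = entropy_categorical(empirical_label_distribution(latent_data.labels))
        assert all(p.prediction_bound <= h_y + 1e-9 for p in sweep)

    def test_empty_grid_rejected(self, latent_data):
        with pytest.raises(ValueError):
            information_plane_sweep(latent_data, VMIBConfig(), [])


class TestProbeRetention:
    def test_latent_equal_to_modality_gives_r2_one(self, latent_data):
        """Stub whose latent IS the modality: a perfect linear decode."""

        class _Identity:
            modality_names = latent_data.modality_names

            def latent_means(self, data, observed=None):
                return data.modalities["m1"]

        r2 = probe_retention(_Identity(), latent_data, "m1")
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_latent_gives_r2_near_zero(self, latent_data):
        rng = np.random.default_rng(0)

        class _Noise:
            modality_names = latent_data.modality_names

            def latent_means(self, data, observed=None):
                return rng.standard_normal((data.n_samples, 6))

        assert probe_retention(_Noise(), latent_data, "m1") <= 0.05

    def test_noisy_modality_compressed_first(self):
        """Raising the compression weight squeezes the weak modality's retention."""
        data = gen_latent_class(
            LatentClassGenConfig(
                n=1200,
                n_classes=3,
                latent_dim=4,
                seed=4,
                modalities=[
                    ModalitySpec("clean", 6, 3.0, [0, 1]),
                    ModalitySpec("noisy", 6, 0.4, [2, 3]),
                ],
            )
        )
        rets = []
        for lam in (1e-3, 0.5):
            cfg = VMIBConfig(
                latent_dim=8, hidden_units=32, epochs=60,
                lambda_compress=lam, dropout_rate=0.0, seed=6,
            )
            model = train_vmib(data, cfg)
            rets.append(probe_retention(model, data, "noisy"))
        assert rets[1] < rets[0]


class TestRepresentationEntropy:
    def test_standard_normal_1d(self, rng):
        z = rng.standard_normal((20000, 1))
        assert representation_entropy(z) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e), abs=0.02
        )

    def test_scaling_law(self, rng):
        z = rng.standard_normal((5000, 3))
        c = 2.5
        assert representation_entropy(c * z) - representation_entropy(z) == pytest.approx(
            3 * np.log(c), abs=1e-3
        )

    def test_correlated_2d_closed_form(self, rng):
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        z = rng.multivariate_normal([0, 0], cov, size=40000)
        expected = 0.5 * np.log((2 * np.pi * np.e) ** 2 * np.linalg.det(cov))
        assert representation_entropy(z) == pytest.approx(expected, abs=0.03)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="ridge"):
            representation_entropy(rng.standard_normal((4, 4)))
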