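"""Task registry, update rules, and the noisy trainer."""

import numpy as np
import pytest
from dataclasses import replace

from driftlab.model import Dataset, NetworkParams, forward, gradient, loss
from driftlab.training import (
    TrainingConfig,
    gd_update,
    label_noise_loss,
    load_training_config,
    make_task,
    sed_update,
    train,
    train_ensemble,
)


class TestMakeTask:
    def test_random_task_uncorrelated_targets(self):
        ds = make_task("random", 4, 4, 10_000, seed=0)
        rho = np.corrcoef(ds.X.T, ds.Y.T)[:4, 4:]
        assert np.all(np.abs(rho) < 0.05)

    def test_smoothed_targets_have_sample_autocorrelation(self):
        raw = make_task("random", 3, 3, 2000, seed=1)
        smooth = make_task("random-smoothed", 3, 3, 2000, seed=1)
        def lag1(Y):
            return np.mean([np.corrcoef(Y[:-1, j], Y[1:, j])[0, 1] for j in range(Y.shape[1])])
        assert lag1(smooth.Y) > 0.5 > abs(lag1(raw.Y))

    def test_abstract_predictive_structure(self):
        ds = make_task("abstract-predictive", 5, 5, 300, seed=2)
        assert ds.positions is not None and ds.positions.shape == (300,)
        # target = observation of the shifted latent: consecutive X rows
        # reproduce Y exactly when dims match
        np.testing.assert_allclose(ds.Y[:-1], ds.X[1:], atol=1e-12)

    def test_corridor_velocity_channel_and_shift(self):
        ds = make_task("corridor", 16, 15, 64, seed=3)
        assert ds.X.shape == (64, 16) and ds.Y.shape == (64, 15)
        assert set(np.sign(ds.X[:, -1])) <= {-1.0, 1.0}
        assert ds.positions is not None

    def test_seed_determinism_and_unknown_kind(self):
        a = make_task("random", 3, 2, 50, seed=9)
        b = make_task("random", 3, 2, 50, seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        with pytest.raises(ValueError):
            make_task("nope", 3, 2, 50, seed=0)


class TestUpdateRules:
    def test_gd_noiseless_is_plain_descent(self):
        rng = np.random.default_rng(0)
        theta, grad = rng.normal(size=10), rng.normal(size=10)
        new = gd_update(theta, grad, lr=0.1, noise_variance=0.0, rng=rng)
        np.testing.assert_allclose(new, theta - 0.1 * grad)
        same = gd_update(theta, np.zeros(10), lr=0.0, noise_variance=0.0, rng=rng)
        np.testing.assert_array_equal(same, theta)

    def test_gd_noise_moments(self):
        rng = np.random.default_rng(1)
        theta = np.zeros(100_000)
        new = gd_update(theta, np.zeros_like(theta), lr=0.1, noise_variance=0.04, rng=rng)
        assert new.var() == pytest.approx(0.04, rel=0.05)
        assert abs(new.mean()) < 3 * 0.2 / np.sqrt(theta.size)

    def test_sed_constant_loss_is_identity(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(size=5)
        new = sed_update(theta, lambda t: 1.0, lr=0.1, perturb_variance=0.01, rng=rng)
        np.testing.assert_array_equal(new, theta)

    def test_sed_mean_update_follows_gradient(self):
        """First-order expansion: E[Δθ] ≈ −η·σ²·∇f for a quadratic loss."""
        A = np.diag([1.0, 3.0])
        f = lambda t: float(t @ A @ t)
        theta = np.array([1.0, -0.5])
        grad = 2 * A @ theta
        rng = np.random.default_rng(3)
        sigma2, lr = 1e-4, 0.5
        deltas = np.array(
            [sed_update(theta, f, lr, sigma2, rng) - theta for _ in range(10_000)]
        )
        expected = -lr * sigma2 * grad
        se = deltas.std(axis=0) / np.sqrt(len(deltas))
        assert np.all(np.abs(deltas.mean(axis=0) - expected) < 4 * se + 1e-7)

    def test_sed_seed_stream_reproducible(self):
        f = lambda t: float(t @ t)
        a = sed_update(np.ones(4), f, 0.1, 0.01, np.random.default_rng(7))
        b = sed_update(np.ones(4), f, 0.1, 0.01, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestLabelNoise:
    def _setup(self):
        rng = np.random.default_rng(4)
        p = NetworkParams.init(3, 2, 5, seed=4)
        data = Dataset(X=rng.normal(size=(20, 3)), Y=rng.normal(size=(20, 2)))
        return p, data

    def test_zero_variance_matches_plain(self):
        p, data = self._setup()
        val, g = label_noise_loss(p, data, 0.0, np.random.default_rng(0))
        assert val == pytest.approx(loss(p, data))
        np.testing.assert_allclose(g, gradient(p, data))

    def test_noisy_gradient_unbiased(self):
        p, data = self._setup()
        rng = np.random.default_rng(5)
        g0 = gradient(p, data)
        gs = np.array([label_noise_loss(p, data, 0.5, rng)[1] for _ in range(10_000)])
        se = gs.std(axis=0) / np.sqrt(len(gs))
        assert np.all(np.abs(gs.mean(axis=0) - g0) < 4 * se + 1e-9)

    def test_noisy_loss_mean_adds_variance_at_zero_residual(self):
        p, _ = self._setup()
        X = np.random.default_rng(6).normal(size=(15, 3))
        _, out = forward(p, X)
        data = Dataset(X=X, Y=out)  # zero residual
        rng = np.random.default_rng(7)
        vals = [label_noise_loss(p, data, 0.3, rng)[0] for _ in range(5000)]
        assert np.mean(vals) == pytest.approx(0.3, rel=0.05)


class TestTrainer:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(algorithm="adam", noise_type="update")
        with pytest.raises(ValueError):
            TrainingConfig(algorithm="sed", noise_type="label")
        with pytest.raises(ValueError):
            TrainingConfig(algorithm="newton")

    def test_zero_learning_rate_trace_constant(self):
        cfg = TrainingConfig(
            learning_rate=0.0, noise_type="none", noise_variance=0.0, steps=200,
            task="random", input_dim=4, output_dim=3, hidden=10, n_samples=16,
        )
        tr = train(cfg)
        np.testing.assert_allclose(tr.raw_loss, tr.raw_loss[0], rtol=1e-12)
        assert np.all(tr.fraction_active_units == tr.fraction_active_units[0])

    def test_trace_is_seed_reproducible(self):
        cfg = TrainingConfig(steps=500, input_dim=9, output_dim=8, hidden=20,
                             n_samples=16, seed=3)
        a, b = train(cfg), train(cfg)
        np.testing.assert_array_equal(a.raw_loss, b.raw_loss)
        np.testing.assert_array_equal(a.checkpoints[-1].m, b.checkpoints[-1].m)

    def test_noiseless_gd_converges_and_keeps_units(self):
        cfg = TrainingConfig(noise_type="none", noise_variance=0.0, steps=20_000,
                             input_dim=9, output_dim=8, hidden=30, n_samples=32, seed=0)
        tr = train(cfg)
        assert tr.loss[-1] < tr.loss[0]
        plateau = np.searchsorted(tr.steps, 2000)
        post = tr.fraction_active_units[plateau:]
        assert post.max() - post.min() <= 1 / 30 + 1e-12  # within one unit

    def test_adam_and_sed_run_and_log(self):
        for algo in ("adam", "rmsprop", "sed"):
            cfg = TrainingConfig(algorithm=algo, noise_type="none",
                                 noise_variance=1e-4 if algo == "sed" else 0.0,
                                 learning_rate=1e-3, steps=300, task="random",
                                 input_dim=4, output_dim=3, hidden=10, n_samples=16)
            tr = train(cfg)
            assert tr.raw_loss[-1] <= tr.raw_loss[0]
            assert len(tr.checkpoints) == len(tr.steps)

    def test_divergence_aborts_with_diagnostic(self):
        cfg = TrainingConfig(learning_rate=50.0, noise_type="none", noise_variance=0.0,
                             steps=2000, task="random", input_dim=4, output_dim=4,
                             hidden=10, n_samples=16)
        with pytest.raises(RuntimeError, match="diverged"):
            train(cfg)

    def test_mean_si_logged_only_for_latent_tasks(self):
        cfg = TrainingConfig(steps=100, task="random", noise_type="none",
                             noise_variance=0.0, input_dim=4, output_dim=3,
                             hidden=10, n_samples=16)
        assert np.all(np.isnan(train(cfg).mean_si))
        cfg2 = TrainingConfig(steps=100, input_dim=9, output_dim=8, hidden=10,
                              n_samples=32)
        assert np.isfinite(train(cfg2).mean_si).all()

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("steps: 123\nhidden: 7\nnoise_variance: 0.02\n")
        cfg = load_training_config(path)
        assert cfg.steps == 123 and cfg.hidden == 7 and cfg.noise_variance == 0.02


class TestEnsemble:
    def test_members_match_serial_statistics(self):
        """Ensemble members follow the same dynamics as serial runs: the
        final losses agree to within the stochastic run-to-run spread."""
        base = TrainingConfig(steps=3000, input_dim=9, output_dim=8, hidden=20,
                              n_samples=32, noise_variance=0.02)
        cfgs = [replace(base, seed=s) for s in range(4)]
        ens = train_ensemble(cfgs)
        ser = [train(c) for c in cfgs]
        e = np.array([t.raw_loss[-1] for t in ens])
        s = np.array([t.raw_loss[-1] for t in ser])
        assert abs(e.mean() - s.mean()) < 3 * (s.std() + e.std()) / np.sqrt(4) + 0.05

    def test_heterogeneous_shapes_rejected(self):
        a = TrainingConfig(steps=10)
        b = replace(a, hidden=50)
        with pytest.raises(ValueError):
            train_ensemble([a, b])

    def test_noiseless_members_are_deterministic_gd(self):
        base = TrainingConfig(steps=400, noise_type="none", noise_variance=0.0,
                              input_dim=9, output_dim=8, hidden=15, n_samples=16, seed=5)
        ens = train_ensemble([base])[0]
        ser = train(base)
        np.testing.assert_allclose(ens.raw_loss, ser.raw_loss, rtol=1e-10)
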