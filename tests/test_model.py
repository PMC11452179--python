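"""Core network, temporal kernels, Poisson loss, training, evaluation."""

import numpy as np
import pytest

from rgctwin import CoreConfig, MovieConfig, RetinaTwin, generate_movie
from rgctwin.nn import Adam, CoreReadout, poisson_loss, temporal_kernel


class TestTemporalKernel:
    def test_zero_weights_give_zero_kernel(self):
        w = temporal_kernel(np.zeros((3, 7)), np.zeros((3, 7)), 1.0, 21)
        assert np.all(w == 0)

    def test_fourier_order_matches_kernel_lengths(self):
        cfg = CoreConfig()
        assert cfg.fourier_k == (21 // 3, 11 // 3) == (7, 3)
        with pytest.raises(ValueError):
            CoreConfig(fourier_k=(8, 3))

    def test_single_cosine_against_scalar_loop(self):
        # brute-force oracle: evaluate the parameterisation element by element
        alpha = np.zeros((1, 7))
        beta = np.zeros((1, 7))
        beta[0, 0] = 1.0
        tau = 1.0
        w = temporal_kernel(alpha, beta, tau, 21)[0]
        t = np.linspace(0, 1, 21)
        expected = np.empty(21)
        for i in range(21):
            eps = 1.0 / (1.0 + np.exp(-(t[i] + 21 * 0.95 * tau)))
            expected[i] = np.cos(2 * np.pi * 1 * tau * t[i] * eps)
        np.testing.assert_allclose(w, expected, atol=1e-10)

    def test_harmonics_scale_frequency(self):
        alpha = np.zeros((1, 3))
        alpha[0, 2] = 1.0  # third harmonic
        w3 = temporal_kernel(alpha, np.zeros((1, 3)), 1.0, 60)[0]
        alpha1 = np.zeros((1, 3))
        alpha1[0, 0] = 1.0
        w1 = temporal_kernel(alpha1, np.zeros((1, 3)), 1.0, 60)[0]
        # third harmonic has ~3x the zero crossings of the first
        assert np.sum(np.diff(np.sign(w3)) != 0) > 2 * np.sum(
            np.diff(np.sign(w1)) != 0
        )

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            temporal_kernel(np.zeros((1, 3)), np.zeros((1, 3)), 0.0, 21)


class TestForward:
    CFG = CoreConfig(n_features=(4, 4), fourier_k=(3, 2))

    def test_output_shape_follows_valid_in_time(self):
        m = CoreReadout(self.CFG, n_neurons=3, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 2, 50, 18, 16))
        pred = m.forward(x)
        assert pred.shape == (2, 3, 50 - 31 + 1)

    def test_output_nonnegative(self):
        m = CoreReadout(self.CFG, n_neurons=2, seed=1)
        x = np.random.default_rng(1).standard_normal((2, 40, 18, 16))
        assert np.all(m.forward(x) >= 0)

    def test_wrong_spatial_size_rejected(self):
        m = CoreReadout(self.CFG, n_neurons=1, seed=0)
        with pytest.raises(ValueError, match="spatial"):
            m.forward(np.zeros((2, 40, 10, 10)))

    def test_too_short_chunk_rejected(self):
        m = CoreReadout(self.CFG, n_neurons=1, seed=0)
        with pytest.raises(ValueError, match="temporal support"):
            m.forward(np.zeros((2, 20, 18, 16)))

    def test_ln_variant_is_linear_before_softplus(self):
        # superposition probe: f(x+y) = f(x) + f(y) - f(0) pre-softplus
        cfg = CoreConfig(n_features=(4, 4), fourier_k=(3, 2),
                         nonlinearity="identity")
        m = CoreReadout(cfg, n_neurons=2, seed=2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 40, 18, 16))
        y = rng.standard_normal((2, 40, 18, 16))

        def pre(v):
            p = m.forward(v)
            return np.log(np.expm1(np.clip(p, 1e-12, None)))  # softplus^-1

        np.testing.assert_allclose(
            pre(x + y), pre(x) + pre(y) - pre(np.zeros_like(x)), atol=1e-6
        )

    def test_cnn_variant_violates_superposition(self):
        m = CoreReadout(self.CFG, n_neurons=2, seed=2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 40, 18, 16))
        y = rng.standard_normal((2, 40, 18, 16))

        def pre(v):
            p = m.forward(v)
            return np.log(np.expm1(np.clip(p, 1e-12, None)))

        resid = pre(x + y) - (pre(x) + pre(y) - pre(np.zeros_like(x)))
        assert np.abs(resid).max() > 1e-3

    def test_stored_kernels_are_space_time_separable(self):
        m = CoreReadout(self.CFG, n_neurons=1, seed=4)
        full = m.full_kernels(1)  # [F, C, Kh, Kw, Kt]
        for f in range(full.shape[0]):
            mat = full[f].reshape(-1, full.shape[-1])
            s = np.linalg.svd(mat, compute_uv=False)
            assert s[1] <= 1e-10 * max(s[0], 1e-30)

    def test_all_zero_input_gives_constant_output(self):
        m = CoreReadout(self.CFG, n_neurons=2, seed=5)
        pred = m.forward(np.zeros((2, 40, 18, 16)))
        assert np.allclose(pred, pred[:, :1])


class TestGradients:
    def test_backward_matches_finite_differences(self):
        cfg = CoreConfig(n_features=(3, 3), fourier_k=(2, 2))
        m = CoreReadout(cfg, n_neurons=2, seed=0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 2, 40, 18, 16))
        y = np.abs(rng.standard_normal((2, 2, 10))) + 0.1

        def loss_of():
            return poisson_loss(m.forward(x), y, average=True)[0]

        pred, cache = m.forward(x, cache_out=True)
        _, dpred = poisson_loss(pred, y, average=True)
        grads, dx = m.backward(dpred, cache, compute_dx=True)
        eps = 1e-6
        for key in ("S1", "alpha1", "tau", "S2", "beta2", "mu", "log_sigma",
                    "W", "bias", "bn1_gamma", "bn2_beta"):
            flat = m.params[key].reshape(-1)
            idx = rng.choice(flat.size, size=min(3, flat.size), replace=False)
            for i in idx:
                old = flat[i]
                flat[i] = old + eps
                lp = loss_of()
                flat[i] = old - eps
                lm = loss_of()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[i]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-9), key
        # input gradient (the MEI path)
        for i in rng.choice(x.size, size=4, replace=False):
            old = x.reshape(-1)[i]
            x.reshape(-1)[i] = old + eps
            lp = loss_of()
            x.reshape(-1)[i] = old - eps
            lm = loss_of()
            x.reshape(-1)[i] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(
                dx.reshape(-1)[i], rel=5e-3, abs=1e-9
            )


class TestPoissonLoss:
    def test_unit_rate_everywhere_gives_count(self):
        pred = np.ones((2, 3, 4))
        target = np.ones_like(pred)
        loss, _ = poisson_loss(pred, target)
        assert loss == pytest.approx(pred.size)

    def test_constant_prediction_minimised_at_target_mean(self):
        # 1-D numeric minimisation oracle
        rng = np.random.default_rng(1)
        target = np.abs(rng.standard_normal(500))
        grid = np.linspace(0.01, 3.0, 3000)
        losses = [poisson_loss(np.full_like(target, g), target)[0]
                  for g in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx(
            target.mean(), abs=2e-3
        )

    def test_gradient_vanishes_at_match(self):
        target = np.abs(np.random.default_rng(2).standard_normal(50)) + 0.1
        _, grad = poisson_loss(target.copy(), target)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            poisson_loss(np.array([0.0, 1.0]), np.ones(2))


class TestAdam:
    def test_converges_on_quadratic(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(500):
            opt.step(params, {"w": 2 * params["w"]})
        np.testing.assert_allclose(params["w"], 0.0, atol=1e-4)

    def test_lr_scale_accelerates_parameter(self):
        p1 = {"a": np.array(10.0), "b": np.array(10.0)}
        opt = Adam(p1, lr=0.01, lr_scale={"b": 10.0})
        for _ in range(50):
            opt.step(p1, {"a": np.array(1.0), "b": np.array(1.0)})
        assert p1["b"] < p1["a"]


@pytest.fixture(scope="module")
def tiny_fit():
    from rgctwin import (PopulationConfig, RecordingConfig, TrainingSchedule,
                         generate_population, simulate_recording)

    movie = generate_movie(MovieConfig(n_clips=8), seed=0)
    cells = generate_population(
        PopulationConfig(counts={"ON": 2}, noise_level=0.0), seed=1
    )
    pack = simulate_recording(
        cells, movie, seed=2,
        config=RecordingConfig(noise_level=0.0, drift_amplitude=0.0),
    )
    twin = RetinaTwin.from_recording(pack, movie)
    sch = TrainingSchedule(n_cycles=1, max_epochs_per_cycle=2,
                           batch_size=8, n_members=2, n_val_clips=2)
    return twin, pack, twin.fit(schedule=sch, seed=7)


class TestTraining:
    def test_same_seed_reproduces_member_weights(self, tiny_fit):
        twin, pack, res = tiny_fit
        res2 = twin.fit(schedule=res.schedule, seed=7)
        for k in res.members[0].params:
            np.testing.assert_array_equal(
                res.members[0].params[k], res2.members[0].params[k]
            )

    def test_ensemble_prediction_is_member_mean(self, tiny_fit):
        twin, pack, res = tiny_fit
        x = twin._movie_z[:, :50]
        member_preds = [m.forward(x) for m in res.members]
        np.testing.assert_allclose(
            res.predict(x), np.mean(member_preds, axis=0), atol=1e-12
        )

    def test_training_log_records_validation_curve(self, tiny_fit):
        _, _, res = tiny_fit
        assert {"cycle", "epoch", "lr", "val_corr", "member"} <= set(
            res.history.columns
        )
        assert res.history.member.nunique() == 2

    def test_evaluation_metrics(self, tiny_fit):
        from rgctwin.model import test_repeat_rates

        twin, pack, res = tiny_fit
        reps = test_repeat_rates(pack, twin.movie)
        ev = res.evaluate(reps)
        assert set(ev.columns) == {"corr_to_mean", "mean_single_trial_corr"}
        assert len(ev) == 2

    def test_summary_mentions_architecture(self, tiny_fit):
        _, _, res = tiny_fit
        text = res.summary()
        assert "ELU" in text and "members: 2" in text


class TestEvaluationMetrics:
    def test_perfect_prediction_gives_unit_correlation(self):
        from rgctwin.metrics import correlation_to_mean

        rng = np.random.default_rng(0)
        reps = rng.standard_normal((3, 200))
        assert correlation_to_mean(reps.mean(axis=0), reps) == pytest.approx(1.0)

    def test_anticorrelated_prediction(self):
        from rgctwin.metrics import correlation_to_mean

        rng = np.random.default_rng(1)
        reps = rng.standard_normal((3, 200))
        pred = -reps.mean(axis=0) + 5.0
        assert correlation_to_mean(pred, reps) == pytest.approx(-1.0)

    def test_constant_prediction_flagged_zero(self):
        from rgctwin.metrics import correlation_to_mean

        reps = np.random.default_rng(2).standard_normal((3, 50))
        with pytest.warns(UserWarning):
            assert correlation_to_mean(np.ones(50), reps) == 0.0
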