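"""Variational machinery: structured sampling, ELBO exactness on a
conjugate toy, penalties, and the training loop contract."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from goaldyn.autodiff import Tensor
from goaldyn.control import ControlParams
from goaldyn.fixtures import FixtureConfig, generate_dataset
from goaldyn.game import GameConfig, TrialTrajectory
from goaldyn.goals import InitialGoalGMM, PotentialModel
from goaldyn.inference import (FixedRecognition, GenerativeModel,
                               PackedTrials, TrainConfig, _draw_sample,
                               _log_joint, complete_trial, elbo_estimate,
                               fit, posterior_sample, prep_trial,
                               regularization_penalty)

D = 3


def synthetic_trial(T=6, seed=0, vmax=(0.02, 0.02, 0.012)):
    """A kinematically consistent random trial."""
    r = np.random.default_rng(seed)
    ups = r.uniform(-0.8, 0.8, size=(T - 1, 3))
    y = np.zeros((T, 3))
    y[0] = (-0.8, 0.0, 0.0)
    for t in range(T - 1):
        y[t + 1] = np.clip(y[t] + np.asarray(vmax) * ups[t], -1, 1)
    return TrialTrajectory(0, y, ups, "truncated",
                           {"session_trend": 0.0, "condition": 0.0})


def diffusion_gen(sigma=0.05, eps=0.05, kappa=1.1, m0=0.0, s0=0.3,
                  d_state=8):
    """Conjugate linear-Gaussian generative model: taps (kappa, 0, 0),
    pure-diffusion goal transitions (lambda -> 0), Gaussian initial goal."""
    def fn(states):
        n = states.shape[0]
        return (np.ones((n, 1)), np.zeros((n, 1, fn.D)),
                np.full((n, 1, fn.D), 1e-14))

    cfg = TrainConfig.desk(sigma=sigma, K=1)
    gen = GenerativeModel(d_state, cfg, np.random.default_rng(0))
    for Dd, agent in ((2, "shooter"), (1, "goalie")):
        f = lambda states, Dd=Dd: (np.ones((states.shape[0], 1)),
                                   np.zeros((states.shape[0], 1, Dd)),
                                   np.full((states.shape[0], 1, Dd), 1e-14))
        pot = PotentialModel("scripted", D=Dd, d_in=d_state, fn=f, sigma=sigma)
        pot.init_gmm = InitialGoalGMM(Dd, 1, means=np.full((1, Dd), m0),
                                      log_sigma=np.log(s0))
        setattr(gen, agent, pot)
    gen.taps.data = np.tile([kappa, 0.0, 0.0], (3, 1))
    gen.log_eps.data = np.log(np.full(3, eps))
    return gen


def dense_conjugate_oracle(packed, sigma, eps, kappa, m0, s0):
    """Exact evidence and posterior of the linear-Gaussian toy, computed
    with dense multivariate-normal algebra (independent of the graph)."""
    T = packed.lengths[0]
    n = T * D
    # prior: g_0 ~ N(m0, s0^2); random walk with step variance sigma^2
    mean_p = np.full(n, m0)
    cov_p = np.zeros((n, n))
    for j in range(D):
        for a in range(T):
            for b in range(T):
                cov_p[a * D + j, b * D + j] = s0 ** 2 \
                    + sigma ** 2 * min(a, b)
    # observations: obs r (r=1..T-1), dim j: u_obs = u_prev + kappa*e_r
    # with u_prev = kappa*e_0 for r=1 and observed u otherwise
    n_obs = (T - 1) * D
    A = np.zeros((n_obs, n))
    b = np.zeros(n_obs)
    u = packed.u_obs
    pos = packed.pos
    for r in range(1, T):
        for j in range(D):
            row = (r - 1) * D + j
            A[row, r * D + j] = kappa
            b[row] -= kappa * pos[r, j]
            if r == 1:
                A[row, j] = kappa
                b[row] -= kappa * pos[0, j]
            else:
                b[row] += u[r - 2, j]
    target = u[:T - 1].ravel()
    S = A @ cov_p @ A.T + eps ** 2 * np.eye(n_obs)
    evidence = multivariate_normal(mean=A @ mean_p + b, cov=S).logpdf(target)
    K = cov_p @ A.T @ np.linalg.inv(S)
    mean_post = mean_p + K @ (target - A @ mean_p - b)
    cov_post = cov_p - K @ A @ cov_p
    return evidence, mean_post, cov_post


def recognition_from_dense(mean_post, cov_post, T):
    """Exact posterior as block-bidiagonal Cholesky blocks."""
    P = np.linalg.inv(cov_post)
    R = np.linalg.cholesky(P)
    dlog = np.zeros((T, D))
    dlow = np.zeros((T, D))
    off = np.zeros((T, D * D))
    for t in range(T):
        blk = R[t * D:(t + 1) * D, t * D:(t + 1) * D]
        dlog[t] = np.log(np.diag(blk))
        dlow[t] = blk[[1, 2, 2], [0, 0, 1]]
        if t >= 1:
            off[t] = R[t * D:(t + 1) * D, (t - 1) * D:t * D].ravel()
    return FixedRecognition(mean_post.reshape(T, D), dlog, dlow, off)


@pytest.fixture(scope="module")
def toy():
    trial = synthetic_trial(T=6, seed=3)
    prepped = prep_trial(trial, (0.02, 0.02, 0.012), lag=2, lead=2)
    packed = PackedTrials([prepped])
    pars = dict(sigma=0.05, eps=0.05, kappa=1.1, m0=0.0, s0=0.3)
    gen = diffusion_gen(**pars)
    evidence, mean_post, cov_post = dense_conjugate_oracle(packed, **pars)
    rec = recognition_from_dense(mean_post, cov_post, packed.lengths[0])
    return packed, gen, rec, evidence, mean_post, cov_post


class TestPosteriorSampling:
    def test_identity_blocks_give_standard_normal_and_iid_logq(self, rng):
        trial = synthetic_trial(T=5)
        prepped = prep_trial(trial, (0.02, 0.02, 0.012), lag=2, lead=2)
        packed = PackedTrials([prepped])
        T = packed.lengths[0]
        m = np.zeros((T, D))
        rec = FixedRecognition(m, np.zeros((T, D)), np.zeros((T, D)),
                               np.zeros((T, D * D)))
        g, logq = _draw_sample(packed, rec, rng)
        oracle = multivariate_normal(mean=np.zeros(T * D)).logpdf(g.data.ravel())
        assert abs(float(logq.data) - oracle) < 1e-10

    def test_tiny_variance_returns_mean_path(self, rng):
        trial = synthetic_trial(T=5)
        prepped = prep_trial(trial, (0.02, 0.02, 0.012), lag=2, lead=2)
        packed = PackedTrials([prepped])
        T = packed.lengths[0]
        m = np.random.default_rng(0).normal(size=(T, D))
        rec = FixedRecognition(m, np.full((T, D), 20.0), np.zeros((T, D)),
                               np.zeros((T, D * D)))
        g, _ = _draw_sample(packed, rec, rng)
        np.testing.assert_allclose(g.data, m, atol=1e-6)

    def test_sample_covariance_matches_dense_inverse_precision(self, rng):
        """Structured draws on a T=3 toy agree with the dense oracle."""
        trial = synthetic_trial(T=3)
        prepped = prep_trial(trial, (0.02, 0.02, 0.012), lag=1, lead=1)
        packed = PackedTrials([prepped])
        T = packed.lengths[0]
        r0 = np.random.default_rng(7)
        dlog = r0.uniform(-0.2, 0.4, (T, D))
        dlow = r0.uniform(-0.5, 0.5, (T, D))
        off = r0.uniform(-0.5, 0.5, (T, D * D))
        rec = FixedRecognition(np.zeros((T, D)), dlog, dlow, off)
        n = 20000
        draws = np.empty((n, T * D))
        for i in range(n):
            g, _ = _draw_sample(packed, rec, rng)
            draws[i] = g.data.ravel()
        # dense assembly of R
        R = np.zeros((T * D, T * D))
        for t in range(T):
            blk = np.diag(np.exp(dlog[t]))
            blk[[1, 2, 2], [0, 0, 1]] = dlow[t]
            R[t * D:(t + 1) * D, t * D:(t + 1) * D] = blk
            if t >= 1:
                R[t * D:(t + 1) * D, (t - 1) * D:t * D] = off[t].reshape(D, D)
        cov = np.linalg.inv(R @ R.T)
        sample_cov = np.cov(draws.T)
        sd = np.sqrt(np.diag(cov))
        for a in range(T * D):
            for b in range(T * D):
                se = np.sqrt((cov[a, b] ** 2 + cov[a, a] * cov[b, b]) / n)
                assert abs(sample_cov[a, b] - cov[a, b]) < 4 * se + 1e-12

    def test_posterior_sample_api_returns_paths_and_logq(self, rng,
                                                         small_dataset):
        from goaldyn.inference import RecognitionModel
        trial = small_dataset.trials[0]
        prepped = prep_trial(trial, (0.02, 0.02, 0.012), lag=4, lead=2)
        rec = RecognitionModel(prepped.feat.shape[1], (8, 8), 4, 2, 0.015,
                               np.random.default_rng(0))
        paths, logqs = posterior_sample(trial, rec, rng, n=3,
                                        vmax=(0.02, 0.02, 0.012))
        assert len(paths) == 3 and logqs.shape == (3,)
        assert paths[0].g.shape == (trial.y.shape[0], 3)


class TestElboConjugate:
    def test_exact_posterior_recovers_evidence_pointwise(self, toy, rng):
        """With q equal to the exact posterior, every Monte-Carlo sample of
        log p(D, g) - log q(g) equals the log evidence identically."""
        packed, gen, rec, evidence, *_ = toy
        for _ in range(10):
            g, logq = _draw_sample(packed, rec, rng)
            val = float(_log_joint(packed, gen, g).data) - float(logq.data)
            assert abs(val - evidence) < 1e-7

    def test_perturbed_posterior_is_a_strict_lower_bound(self, toy, rng):
        packed, gen, rec, evidence, mean_post, cov_post = toy
        worse = FixedRecognition(rec.m + 0.05, rec.dlog + 0.3, rec.dlow,
                                 rec.off)
        vals = [elbo_estimate(None, gen, worse, 1, rng, packed=packed)
                for _ in range(40)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) < evidence - 2 * se

    def test_mc_variance_halves_when_samples_double(self, toy, rng):
        packed, gen, rec, evidence, mean_post, cov_post = toy
        worse = FixedRecognition(rec.m + 0.02, rec.dlog + 0.2, rec.dlow,
                                 rec.off)
        v1 = [elbo_estimate(None, gen, worse, 1, rng, packed=packed)
              for _ in range(200)]
        v2 = [elbo_estimate(None, gen, worse, 2, rng, packed=packed)
              for _ in range(200)]
        ratio = np.var(v1) / np.var(v2)
        assert 1.4 < ratio < 2.9


class TestPenalties:
    def test_component_variance_penalty_arithmetic(self):
        gen = diffusion_gen()
        gen.log_eps.data = np.log(np.full(3, 1e-12))
        cfg = TrainConfig(gamma=0.1, hinge_margin=1.5, hinge_weight=100.0)
        lam = np.full((4, 2), 0.1)
        pen = regularization_penalty(gen, lam, np.zeros((4, 2)), cfg)
        assert abs(pen - (-0.1 / 0.1) * 8) < 1e-6

    def test_hinge_linear_beyond_margin(self):
        gen = diffusion_gen()
        gen.log_eps.data = np.log(np.full(3, 1e-12))
        cfg = TrainConfig(hinge_weight=1.0)
        pen_in = regularization_penalty(gen, np.ones((1, 1)),
                                        np.array([[1.4]]), cfg)
        pen_out = regularization_penalty(gen, np.ones((1, 1)),
                                         np.array([[1.6]]), cfg)
        assert abs((pen_in - pen_out) - 0.1) < 1e-9

    def test_eps_penalty_scale(self):
        gen = diffusion_gen()
        gen.log_eps.data = np.log(np.full(3, 1e-4))
        cfg = TrainConfig(rho=1e5, gamma=1e-30, hinge_weight=0.0)
        pen = regularization_penalty(gen, np.ones((1, 1)), np.zeros((1, 1)),
                                     cfg)
        assert abs(pen - (-10.0 * 3)) < 1e-6

    def test_penalties_vanish_in_benign_limits(self):
        gen = diffusion_gen()
        gen.log_eps.data = np.log(np.full(3, 1e-300))
        cfg = TrainConfig()
        pen = regularization_penalty(gen, np.full((5, 2), 1e12),
                                     np.zeros((5, 2)), cfg)
        assert -1e-9 < pen <= 0.0


class TestFit:
    def _cfg(self, **kw):
        base = dict(warmup_epochs=2, main_epochs=3, K=2, hidden=(8,),
                    rec_hidden=(8, 8), lag=3, lead=2, batch_size=10,
                    holdout_frac=0.2, stop_tol=0.0, seed=5)
        base.update(kw)
        return TrainConfig.desk(**base)

    def test_same_seed_same_history(self, small_dataset):
        trials = small_dataset.trials[:14]
        game = small_dataset.truth.game
        a = fit(trials, self._cfg(), game=game)
        b = fit(trials, self._cfg(), game=game)
        assert len(a.history) == len(b.history)
        for ha, hb in zip(a.history, b.history):
            assert ha["train_elbo"] == hb["train_elbo"]

    def test_warmup_freezes_taps_then_gradient_flows(self, small_dataset):
        trials = small_dataset.trials[:14]
        model = fit(trials, self._cfg(), game=small_dataset.truth.game)
        hist = model.history
        prop = np.tile([1.0, -1.0, 0.0], (3, 1))
        assert np.array_equal(hist[1]["taps"], prop)
        assert not np.array_equal(hist[-1]["taps"], prop)

    def test_training_elbo_improves_on_fixture_data(self, small_dataset):
        cfg = self._cfg(warmup_epochs=4, main_epochs=8)
        model = fit(small_dataset.trials, cfg, game=small_dataset.truth.game)
        elbos = [h["train_elbo"] for h in model.history]
        assert np.mean(elbos[-3:]) > np.mean(elbos[:3])


class TestCompleteTrial:
    def _deterministic_model(self, sigma=1e-9):
        """Single-mode constant potential, tight recognition, eps -> 0."""
        game = GameConfig()
        cfg = TrainConfig.desk(K=1, sigma=max(sigma, 1e-12))
        gen = GenerativeModel(8, cfg, np.random.default_rng(0))
        for Dd, agent, mode in ((2, "shooter", [0.9, 0.3]),
                                (1, "goalie", [0.0])):
            f = lambda states, Dd=Dd, mode=mode: (
                np.ones((states.shape[0], 1)),
                np.tile(mode, (states.shape[0], 1, 1)),
                np.full((states.shape[0], 1, Dd), 50.0))
            pot = PotentialModel("scripted", D=Dd, d_in=8, fn=f, sigma=sigma)
            setattr(gen, agent, pot)
        gen.log_eps.data = np.log(np.full(3, 1e-12))
        return gen, game

    def _prefix(self, T=12):
        return synthetic_trial(T=T, seed=11)

    def _tight_rec(self, T, m):
        return FixedRecognition(m, np.full((T, D), 25.0), np.zeros((T, D)),
                                np.zeros((T, D * D)))

    def test_deterministic_limit_gives_identical_completions(self, rng):
        from goaldyn.inference import FittedModel
        gen, game = self._deterministic_model()
        prefix = self._prefix()
        t0 = 6
        m = np.tile([0.5, 0.1, 0.0], (t0 + 1, 1))
        model = FittedModel(gen, self._tight_rec(t0 + 1, m), [], None, game,
                            game.vmax_arr)
        comps, gps = complete_trial(prefix, model, n=4, t0=t0, rng=rng)
        for c in comps[1:]:
            np.testing.assert_allclose(c.y, comps[0].y, atol=1e-5)

    def test_bottom_clamped_goalie_moves_down(self, rng):
        from goaldyn.inference import FittedModel
        gen, game = self._deterministic_model(sigma=1e-3)
        prefix = self._prefix()
        t0 = 6
        m = np.tile([0.5, 0.1, 0.0], (t0 + 1, 1))
        model = FittedModel(gen, self._tight_rec(t0 + 1, m), [], None, game,
                            game.vmax_arr)
        comps, _ = complete_trial(prefix, model, n=50, t0=t0, rng=rng,
                                  clamp={"goalie": -1.0})
        down = [np.mean(np.diff(c.y[t0:t0 + 6, 2])) < 0 for c in comps]
        assert np.mean(down) >= 0.9

    def test_clamp_outside_margin_rejected(self, rng):
        from goaldyn.inference import FittedModel
        gen, game = self._deterministic_model()
        model = FittedModel(gen, self._tight_rec(7, np.zeros((7, 3))), [],
                            None, game, game.vmax_arr)
        with pytest.raises(ValueError, match="1.5"):
            complete_trial(self._prefix(), model, n=1, t0=6, rng=rng,
                           clamp={"goalie": -1.6})

    def test_early_t0_rejected(self, rng):
        from goaldyn.inference import FittedModel
        gen, game = self._deterministic_model()
        model = FittedModel(gen, self._tight_rec(7, np.zeros((7, 3))), [],
                            None, game, game.vmax_arr)
        with pytest.raises(ValueError):
            complete_trial(self._prefix(), model, n=1, t0=2, rng=rng)

    def test_noiseless_self_consistency(self, rng):
        """Completing a model-generated prefix with its true goals and
        eps = 0 reproduces the original suffix."""
        gen, game = self._deterministic_model(sigma=1e-12)
        from goaldyn.fixtures import _rollout
        from goaldyn.inference import FittedModel

        cfg = FixtureConfig(n_trials=1, max_steps=60, seed=2,
                            true_eps=(0.0,) * 3, true_sigma=1e-12,
                            game=game)
        control = ControlParams(taps=np.tile([1.0, -1.0, 0.0], (3, 1)),
                                eps=np.full(3, 1e-300))
        trial, gp = _rollout(0, cfg, gen.shooter, gen.goalie, control,
                             {"session_trend": 0.0, "condition": 0.0},
                             np.random.default_rng(4))
        gen.taps.data = control.taps.copy()
        t0 = 8
        rec = self._tight_rec(t0 + 1, gp.g[:t0 + 1])
        model = FittedModel(gen, rec, [], None, game, game.vmax_arr)
        comps, _ = complete_trial(trial, model, n=1, t0=t0, rng=rng,
                                  eps_override=np.zeros(3))
        T = min(comps[0].y.shape[0], trial.y.shape[0])
        np.testing.assert_allclose(comps[0].y[:T], trial.y[:T], atol=1e-6)
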