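"""Goal-process mechanics: mixture parameters, conditional transitions,
potential surfaces and the initial-condition bootstrap."""

import numpy as np
import pytest
from scipy.stats import norm

from goaldyn.control import ControlParams
from goaldyn.goals import (InitialGoalGMM, PotentialModel, bootstrap_initial,
                           conditional_goal_sample, gmm_params,
                           goal_transition_logpdf, potential_surface)


def scripted(K, D, w=None, mu=None, lam=None):
    """Constant-parameter scripted potential."""
    w = np.ones(K) / K if w is None else np.asarray(w, dtype=float)
    mu = np.zeros((K, D)) if mu is None else np.asarray(mu, dtype=float)
    lam = np.ones((K, D)) if lam is None else np.asarray(lam, dtype=float)

    def fn(states):
        n = states.shape[0]
        return (np.tile(w, (n, 1)), np.tile(mu, (n, 1, 1)),
                np.tile(lam, (n, 1, 1)))
    return PotentialModel("scripted", D=D, d_in=8, K=K, fn=fn, sigma=0.01)


class TestGmmParams:
    def test_softmax_softplus_at_zero_outputs(self):
        """All-zero raw outputs give uniform weights and lambda = ln 2."""
        model = PotentialModel("linear", D=2, d_in=4, K=4,
                               rng=np.random.default_rng(0))
        # zero the affine map entirely
        model.net.weights[0].data[:] = 0.0
        model.net.biases[0].data[:] = 0.0
        w, mu, lam = gmm_params(np.zeros(4), model)
        np.testing.assert_allclose(w, 0.25)
        np.testing.assert_allclose(lam, np.log(2.0), atol=1e-12)
        np.testing.assert_allclose(mu, 0.0)

    def test_single_gaussian_variant_has_unit_weight(self):
        model = PotentialModel("nn_single", D=1, d_in=4, K=7,
                               hidden=(8,), rng=np.random.default_rng(0))
        w, mu, lam = gmm_params(np.zeros(4), model)
        assert w.shape == (1,)
        np.testing.assert_allclose(w, 1.0)

    def test_linear_variant_constant_for_zero_weights(self):
        model = PotentialModel("linear", D=1, d_in=4, K=2,
                               rng=np.random.default_rng(0))
        model.net.weights[0].data[:] = 0.0
        a = gmm_params(np.zeros(4), model)
        b = gmm_params(np.ones(4) * 5, model)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x, y)

    def test_weights_on_simplex_lambda_positive(self):
        model = PotentialModel("nn_gmm", D=2, d_in=6, K=5, hidden=(16,),
                               rng=np.random.default_rng(1))
        states = np.random.default_rng(2).normal(size=(50, 6))
        w, mu, lam = model.gmm_params_np(states)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(lam > 0)


class TestConditionalSample:
    def test_small_lambda_is_pure_diffusion(self, rng):
        model = scripted(1, 2, lam=np.full((1, 2), 1e-12))
        params = tuple(p[0] for p in model.gmm_params_np(np.zeros((1, 8))))
        draws = np.array([conditional_goal_sample([0.3, -0.2], params, 0.05, rng)[0]
                          for _ in range(4000)])
        np.testing.assert_allclose(draws.mean(axis=0), [0.3, -0.2], atol=0.01)
        np.testing.assert_allclose(draws.std(axis=0), 0.05, rtol=0.1)

    def test_large_lambda_pins_to_mode(self, rng):
        model = scripted(1, 1, mu=[[0.7]], lam=[[1e9]])
        params = tuple(p[0] for p in model.gmm_params_np(np.zeros((1, 8))))
        g, k = conditional_goal_sample([0.0], params, 0.05, rng)
        assert abs(g[0] - 0.7) < 1e-3
        assert k == 0

    def test_unit_lambda_interpolates(self, rng):
        """lambda=1, g_prev=0, mu=1: mean 1/2 and variance sigma^2/2."""
        model = scripted(1, 1, mu=[[1.0]], lam=[[1.0]])
        params = tuple(p[0] for p in model.gmm_params_np(np.zeros((1, 8))))
        draws = np.array([conditional_goal_sample([0.0], params, 0.05, rng)[0][0]
                          for _ in range(8000)])
        assert abs(draws.mean() - 0.5) < 0.003
        assert abs(draws.var() - 0.05 ** 2 / 2) < 2e-4


class TestTransitionLogpdf:
    def test_single_component_matches_gaussian(self):
        sigma, lam, mu = 0.05, 0.8, 0.4
        params = (np.ones(1), np.array([[mu]]), np.array([[lam]]))
        mean = (0.1 + lam * mu) / (1 + lam)
        sd = sigma / np.sqrt(1 + lam)
        mine = goal_transition_logpdf([0.12], [0.1], params, sigma)
        assert abs(mine - norm(mean, sd).logpdf(0.12)) < 1e-12

    def test_symmetric_mixture_invariant_under_component_swap(self):
        params = (np.array([0.5, 0.5]), np.array([[0.5], [-0.5]]),
                  np.array([[0.3], [0.3]]))
        a = goal_transition_logpdf([0.0], [0.0], params, 0.05)
        swapped = (np.array([0.5, 0.5]), np.array([[-0.5], [0.5]]),
                   np.array([[0.3], [0.3]]))
        b = goal_transition_logpdf([0.0], [0.0], swapped, 0.05)
        assert abs(a - b) < 1e-12

    def test_density_integrates_to_one(self):
        """Trapezoid-rule oracle over a 1-D grid."""
        r = np.random.default_rng(6)
        w = r.dirichlet(np.ones(3))
        mu = r.uniform(-0.5, 0.5, (3, 1))
        lam = r.uniform(0.1, 2.0, (3, 1))
        sigma = 0.05
        grid = np.linspace(-1.5, 1.5, 20001)
        lp = [goal_transition_logpdf([g], [0.1], (w, mu, lam), sigma)
              for g in grid]
        integral = np.trapezoid(np.exp(lp), grid)
        assert abs(integral - 1.0) < 1e-6

    def test_sampler_moments_match_density(self, rng):
        """10^5 draws agree with analytic mixture moments within 4 SE."""
        w = np.array([0.3, 0.7])
        mu = np.array([[0.6], [-0.4]])
        lam = np.array([[0.5], [1.5]])
        sigma, g_prev = 0.05, np.array([0.1])
        n = 100_000
        params = (w, mu, lam)
        draws = np.array([conditional_goal_sample(g_prev, params, sigma, rng)[0][0]
                          for _ in range(n)])
        means = ((g_prev + lam * mu) / (1 + lam)).ravel()
        variances = (sigma ** 2 / (1 + lam)).ravel()
        m_true = np.dot(w, means)
        v_true = np.dot(w, variances + means ** 2) - m_true ** 2
        se_m = np.sqrt(v_true / n)
        assert abs(draws.mean() - m_true) < 4 * se_m
        m4 = np.dot(w, 3 * variances ** 2 + 6 * variances * means ** 2 + means ** 4)
        se_v = np.sqrt(max(m4 - v_true ** 2, 0) / n)
        assert abs(draws.var() - v_true) < 4 * se_v

    def test_constant_potential_gives_ar1_autocorrelation(self, rng):
        """Fixed lambda, mu: goals follow an AR(1) with coefficient 1/(1+lambda)."""
        lam, mu, sigma = 1.5, 0.0, 0.05
        phi = 1 / (1 + lam)
        g = 0.0
        xs = []
        params = (np.ones(1), np.array([[mu]]), np.array([[lam]]))
        for _ in range(20000):
            g = conditional_goal_sample([g], params, sigma, rng)[0][0]
            xs.append(g)
        xs = np.array(xs[500:])
        rho = np.corrcoef(xs[:-1], xs[1:])[0, 1]
        assert abs(rho - phi) < 0.02


class TestPotentialSurface:
    def test_single_component_peak_at_mode(self):
        model = scripted(1, 2, mu=[[0.3, -0.4]], lam=[[2.0, 2.0]])
        gx = np.linspace(-1, 1, 41)
        gy = np.linspace(-1, 1, 41)
        surf = potential_surface(np.zeros(8), model, (gx, gy))
        i, j = np.unravel_index(np.argmax(surf), surf.shape)
        assert abs(gx[i] - 0.3) <= 0.051
        assert abs(gy[j] + 0.4) <= 0.051

    def test_two_separated_components_give_two_maxima(self):
        model = scripted(2, 1, mu=[[0.6], [-0.6]], lam=[[50.0], [50.0]])
        ax = np.linspace(-1, 1, 201)
        surf = potential_surface(np.zeros(8), model, ax)
        interior = (surf[1:-1] > surf[:-2]) & (surf[1:-1] > surf[2:])
        assert interior.sum() == 2

    def test_values_match_direct_mixture_formula(self):
        r = np.random.default_rng(8)
        w = r.dirichlet(np.ones(3))
        mu = r.uniform(-0.5, 0.5, (3, 2))
        lam = r.uniform(0.5, 3.0, (3, 2))
        model = scripted(3, 2, w=w, mu=mu, lam=lam)
        pts = np.array([[0.1], [0.2]])
        surf = potential_surface(np.zeros(8), model, (pts[0], pts[1]))
        g = np.array([0.1, 0.2])
        s2 = model.sigma ** 2
        direct = sum(
            w[k] * np.prod(np.sqrt(lam[k] / (2 * np.pi * s2))
                           * np.exp(-lam[k] * (g - mu[k]) ** 2 / (2 * s2)))
            for k in range(3))
        assert abs(surf[0, 0] - direct) < 1e-12 * max(1, direct)


class TestBootstrap:
    def _models(self, init_at=None):
        shooter = scripted(1, 2, mu=[[0.9, 0.0]], lam=[[0.5, 0.5]])
        goalie = scripted(1, 1, mu=[[0.0]], lam=[[1.0]])
        if init_at is not None:
            shooter.init_gmm = InitialGoalGMM(2, 1, means=init_at[None, :2],
                                              log_sigma=np.log(1e-9))
            goalie.init_gmm = InitialGoalGMM(1, 1, means=init_at[None, 2:],
                                             log_sigma=np.log(1e-9))
        return shooter, goalie

    def test_init_gmm_at_position_gives_zero_error_and_control(self, rng):
        y0 = np.array([-0.8, 0.0, 0.0])
        shooter, goalie = self._models(init_at=y0)
        control = ControlParams.proportional()
        g0, g1, u0, u1, e_hist = bootstrap_initial(
            y0, shooter, goalie, control, rng, noise=False)
        np.testing.assert_allclose(g0, y0, atol=1e-6)
        np.testing.assert_allclose(u0, 0.0, atol=1e-6)

    def test_proportional_taps_give_u0_equals_e0(self, rng):
        y0 = np.array([-0.8, 0.0, 0.0])
        shooter, goalie = self._models()
        control = ControlParams.proportional()
        g0, g1, u0, u1, e_hist = bootstrap_initial(
            y0, shooter, goalie, control, rng, noise=False)
        np.testing.assert_allclose(u0, g0 - y0, atol=1e-12)
        # and u1 follows the three-tap recursion with e_{-1} = 0
        np.testing.assert_allclose(u1, u0 + (g1 - y0) - (g0 - y0), atol=1e-12)
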