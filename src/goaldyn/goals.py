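"""Stochastic goal process: state-dependent Gaussian-mixture potential.

Each player's latent goal g_t (2-D for the shooter, 1-D for the goalie)
follows a Markov process balancing a smoothness ("kinetic") term against a
state-dependent potential whose exponential is a Gaussian mixture,

    e^V(g; s) ~ sum_k w_k(s) N(g; mu_k(s), sigma^2 / lambda_k(s)),

with (w, mu, lambda) produced by a neural network from the state vector
(softmax on w, softplus on lambda).  Conditioned on the previous goal the
transition is again a Gaussian mixture: component k is drawn from
Categorical(w) and then, elementwise per goal dimension j,

    g_j | k ~ N( (g_prev_j + lambda_kj mu_kj) / (1 + lambda_kj),
                 sigma^2 / (1 + lambda_kj) ).

The diffusion scale sigma is fixed (default 1e-3) and beta = sigma^-2.

Variants: ``nn_gmm`` (full model), ``nn_single`` (K = 1), ``linear``
(affine map instead of a network) and ``scripted`` (closed-form parameter
functions, used by the synthetic-fixture generator and by unit oracles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .autodiff import Tensor
from .control import ControlParams
from .nets import MLP

__all__ = ["PotentialModel", "InitialGoalGMM", "GoalPath", "gmm_params",
           "conditional_goal_sample", "goal_transition_logpdf",
           "potential_surface", "bootstrap_initial"]

VARIANTS = ("nn_gmm", "nn_single", "linear", "scripted")
DEFAULT_SIGMA = 1e-3
GAUSS_CONST = 0.5 * np.log(2.0 * np.pi)

# goal dimension -> index into the observed position vector
SHOOTER_DIMS = np.array([0, 1])   # (x_puck, y_puck)
GOALIE_DIMS = np.array([2])       # (y_goalie,)


@dataclass
class GoalPath:
    """Latent goal time series for one trial (T, D_total)."""

    g: np.ndarray
    component_ids: np.ndarray | None = None
    provenance: str = "generated"

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=np.float64)
        if not np.all(np.isfinite(self.g)):
            raise ValueError("goal path contains non-finite values")


class InitialGoalGMM:
    """K0-component diagonal GMM over the initial goal g_0 of one agent."""

    def __init__(self, D: int, K0: int = 20, rng: np.random.Generator | None = None,
                 means: np.ndarray | None = None, log_sigma: float = np.log(0.3)):
        rng = rng or np.random.default_rng(0)
        self.D, self.K0 = D, K0
        self.logits = Tensor(np.zeros(K0), requires_grad=True)
        if means is None:
            means = rng.uniform(-0.8, 0.8, size=(K0, D))
        self.means = Tensor(np.asarray(means, dtype=np.float64), requires_grad=True)
        self.log_sig = Tensor(np.full((K0, D), log_sigma), requires_grad=True)

    @property
    def params(self):
        return [self.logits, self.means, self.log_sig]

    def _np(self):
        w = softmax(self.logits.data)
        return w, self.means.data, np.exp(self.log_sig.data)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        w, mu, sig = self._np()
        k = rng.choice(self.K0, p=w)
        return mu[k] + sig[k] * rng.standard_normal(self.D)

    def logpdf(self, g: np.ndarray) -> float:
        w, mu, sig = self._np()
        g = np.asarray(g, dtype=np.float64)
        lp = (-np.log(sig) - GAUSS_CONST
              - 0.5 * ((g - mu) / sig) ** 2).sum(axis=1)
        return float(logsumexp(np.log(w) + lp))

    def logpdf_t(self, g: Tensor) -> Tensor:
        """Log-density for a batch of rows (n, D), as a Tensor (n,)."""
        logw = self.logits.softmax().log()                       # (K0,)
        sig = self.log_sig.exp()                                 # (K0, D)
        diff = (g.reshape(-1, 1, self.D) - self.means) / sig
        lp = (-self.log_sig - GAUSS_CONST - 0.5 * diff * diff).sum(axis=2)
        return (lp + logw).logsumexp(axis=1)

    def state_dict(self) -> dict:
        return {"D": self.D, "K0": self.K0, "logits": self.logits.data,
                "means": self.means.data, "log_sig": self.log_sig.data}

    @classmethod
    def from_state(cls, d: dict) -> "InitialGoalGMM":
        obj = cls.__new__(cls)
        obj.D, obj.K0 = int(d["D"]), int(d["K0"])
        obj.logits = Tensor(np.asarray(d["logits"]), requires_grad=True)
        obj.means = Tensor(np.asarray(d["means"]), requires_grad=True)
        obj.log_sig = Tensor(np.asarray(d["log_sig"]), requires_grad=True)
        return obj


class PotentialModel:
    """State-dependent GMM potential for one agent's goal dimensions.

    The network maps a d-dimensional state to K*(2D+1) raw outputs, split
    into mixture logits (K), means (K*D) and raw precisions (K*D); the
    softmax/softplus post-processing guarantees sum_k w_k = 1 and
    lambda > 0.
    """

    def __init__(self, variant: str, D: int, d_in: int, K: int = 20,
                 hidden: tuple = (128, 128), sigma: float = DEFAULT_SIGMA,
                 rng: np.random.Generator | None = None,
                 fn=None, init_gmm: InitialGoalGMM | None = None,
                 K0: int | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        rng = rng or np.random.default_rng(0)
        self.variant = variant
        self.D, self.d_in, self.sigma = D, d_in, float(sigma)
        self.K = 1 if variant == "nn_single" else K
        self.fn = fn
        if variant == "scripted":
            if fn is None:
                raise ValueError("scripted variant requires fn")
            self.net = None
        else:
            n_out = self.K * (2 * self.D + 1)
            sizes = [d_in, n_out] if variant == "linear" else [d_in, *hidden, n_out]
            # start mixture means spread over the screen and lambda small:
            # the goal process begins near its pure-diffusion limit, so the
            # untrained potential exerts almost no (initially arbitrary) pull
            bias = np.zeros(n_out)
            bias[self.K:self.K + self.K * self.D] = rng.uniform(-0.5, 0.5, self.K * self.D)
            bias[self.K + self.K * self.D:] = -3.0
            self.net = MLP(sizes, rng, out_weight_scale=0.1, out_bias=bias)
        self.init_gmm = init_gmm or InitialGoalGMM(D, K0 or self.K, rng)

    @property
    def beta(self) -> float:
        return self.sigma ** -2

    @property
    def params(self):
        ps = list(self.init_gmm.params)
        if self.net is not None:
            ps.extend(self.net.params)
        return ps

    # ------------------------------------------------------------- forward
    def _split(self, raw):
        K, D = self.K, self.D
        return raw[:, :K], raw[:, K:K + K * D], raw[:, K + K * D:]

    def gmm_params_np(self, states: np.ndarray):
        """(w, mu, lam) as numpy arrays for a batch of states (n, d)."""
        states = np.atleast_2d(np.asarray(states, dtype=np.float64))
        if self.variant == "scripted":
            w, mu, lam = self.fn(states)
            return (np.asarray(w, dtype=np.float64),
                    np.asarray(mu, dtype=np.float64),
                    np.asarray(lam, dtype=np.float64))
        raw = self.net.forward_np(states)
        if not np.all(np.isfinite(raw)):
            norms = [float(np.linalg.norm(w.data)) for w in self.net.weights]
            raise FloatingPointError(
                f"non-finite potential-network output; weight norms {norms}")
        w_raw, mu_raw, lam_raw = self._split(raw)
        n = states.shape[0]
        w = softmax(w_raw, axis=1)
        mu = mu_raw.reshape(n, self.K, self.D)
        lam = np.logaddexp(0.0, lam_raw).reshape(n, self.K, self.D)
        return w, mu, lam

    def gmm_params_t(self, states: Tensor):
        """(log_w, mu, lam) as Tensors for the training graph."""
        if self.variant == "scripted":
            w, mu, lam = self.gmm_params_np(states.data)
            return (Tensor(np.log(np.maximum(w, 1e-300))),
                    Tensor(mu.reshape(w.shape[0], -1)),
                    Tensor(lam.reshape(w.shape[0], -1)))
        raw = self.net(states)
        w_raw, mu_raw, lam_raw = self._split(raw)
        log_w = w_raw.softmax(axis=1).log()
        lam = lam_raw.softplus()
        return log_w, mu_raw, lam          # mu/lam flat (n, K*D)

    def state_dict(self) -> dict:
        d = {"variant": self.variant, "D": self.D, "d_in": self.d_in,
             "K": self.K, "sigma": self.sigma,
             "init_gmm": self.init_gmm.state_dict()}
        if self.net is not None:
            d["net"] = self.net.state_dict()
        return d

    @classmethod
    def from_state(cls, d: dict) -> "PotentialModel":
        obj = cls.__new__(cls)
        obj.variant = d["variant"]
        obj.D, obj.d_in = int(d["D"]), int(d["d_in"])
        obj.K, obj.sigma = int(d["K"]), float(d["sigma"])
        obj.fn = None
        obj.net = MLP.from_state(d["net"]) if "net" in d else None
        obj.init_gmm = InitialGoalGMM.from_state(d["init_gmm"])
        return obj


def gmm_params(state, model: PotentialModel):
    """Post-processed mixture parameters (w, mu, lam) at one state.

    Returns ``w`` on the K-simplex, ``mu`` (K, D) unconstrained and
    ``lam`` (K, D) strictly positive.
    """
    state = np.asarray(state, dtype=np.float64)
    single = state.ndim == 1
    w, mu, lam = model.gmm_params_np(state)
    if single:
        return w[0], mu[0], lam[0]
    return w, mu, lam


def conditional_goal_sample(g_prev, params, sigma: float,
                            rng: np.random.Generator):
    """Draw (g_t, k): component from Categorical(w), then the elementwise
    Gaussian interpolating kinetic and potential terms."""
    w, mu, lam = params
    g_prev = np.asarray(g_prev, dtype=np.float64)
    k = int(rng.choice(len(w), p=np.asarray(w) / np.sum(w)))
    mean = (g_prev + lam[k] * mu[k]) / (1.0 + lam[k])
    std = sigma / np.sqrt(1.0 + lam[k])
    return mean + std * rng.standard_normal(g_prev.shape), k


def goal_transition_logpdf(g, g_prev, params, sigma: float) -> float:
    """log p(g_t | g_{t-1}, s_t): mixture of component-wise Gaussians."""
    w, mu, lam = params
    g = np.asarray(g, dtype=np.float64)
    g_prev = np.asarray(g_prev, dtype=np.float64)
    mean = (g_prev + lam * mu) / (1.0 + lam)              # (K, D)
    var = sigma ** 2 / (1.0 + lam)
    lp = (-0.5 * np.log(2 * np.pi * var)
          - 0.5 * (g - mean) ** 2 / var).sum(axis=-1)     # (K,)
    return float(logsumexp(np.log(np.maximum(w, 1e-300)) + lp))


def potential_surface(state, model: PotentialModel, grid):
    """Evaluate e^V (up to its overall constant) on a goal grid.

    ``grid``: for a 2-D agent a pair of 1-D axes (gx, gy) -> matrix of
    shape (len(gx), len(gy)); for a 1-D agent a single axis -> vector.
    """
    w, mu, lam = gmm_params(state, model)
    s2 = model.sigma ** 2
    if model.D == 1:
        ax = np.asarray(grid, dtype=np.float64).ravel()
        pts = ax[:, None]
    else:
        gx = np.asarray(grid[0], dtype=np.float64).ravel()
        gy = np.asarray(grid[1], dtype=np.float64).ravel()
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    # mixture density with per-component variance sigma^2 / lambda
    var = s2 / lam                                          # (K, D)
    lp = (-0.5 * np.log(2 * np.pi * var)
          - 0.5 * (pts[:, None, :] - mu) ** 2 / var).sum(axis=-1)
    vals = np.exp(logsumexp(np.log(np.maximum(w, 1e-300)) + lp, axis=1))
    if model.D == 1:
        return vals
    return vals.reshape(len(gx), len(gy))


def bootstrap_initial(y_init, shooter: PotentialModel, goalie: PotentialModel,
                      control: ControlParams, rng: np.random.Generator,
                      covariates: dict | None = None, noise: bool = True):
    """Initialize goals and control for a rollout (five-step bootstrap).

    Before the first observation the position is frozen at ``y_init``,
    goals equal the position (zero error, zero control).  Then g_0 is
    drawn from the initial-goal GMM, giving e_0 and u_0 = L0 * e_0; g_1 is
    drawn from the conditional transition at the initial state, giving
    e_1 and u_1 = u_0 + L0 e_1 + L1 e_0.

    Returns ``(g0, g1, u0, u1, e_hist)`` with goals/errors as 3-vectors in
    goal-dimension order (shooter x, shooter y, goalie y) and ``e_hist``
    ordered newest-first (e_1, e_0, 0).
    """
    y_init = np.asarray(y_init, dtype=np.float64)
    pos = y_init  # goal dims align with (x_puck, y_puck, y_goalie)
    g0 = np.empty(3)
    g0[SHOOTER_DIMS] = shooter.init_gmm.sample(rng)
    g0[GOALIE_DIMS] = goalie.init_gmm.sample(rng)
    e0 = g0 - pos
    u0 = control.taps[:, 0] * e0
    if noise:
        u0 = u0 + control.eps * rng.standard_normal(3)

    state = np.concatenate([y_init, np.zeros(3),
                            np.asarray(list((covariates or {}).values()), dtype=np.float64)])
    g1 = np.empty(3)
    ps = shooter.gmm_params_np(state[None, :])
    g1[SHOOTER_DIMS], _ = conditional_goal_sample(
        g0[SHOOTER_DIMS], (ps[0][0], ps[1][0], ps[2][0]), shooter.sigma, rng)
    pg = goalie.gmm_params_np(state[None, :])
    g1[GOALIE_DIMS], _ = conditional_goal_sample(
        g0[GOALIE_DIMS], (pg[0][0], pg[1][0], pg[2][0]), goalie.sigma, rng)
    e1 = g1 - pos
    u1 = u0 + control.taps[:, 0] * e1 + control.taps[:, 1] * e0
    if noise:
        u1 = u1 + control.eps * rng.standard_normal(3)
    e_hist = np.stack([e1, e0, np.zeros(3)])
    return g0, g1, u0, u1, e_hist
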