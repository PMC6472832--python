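"""Black-box variational inference for the latent-goal model.

The approximate posterior over each trial's goal path is a structured
Gaussian whose precision is block-tridiagonal: neural networks map a
lagged window of the observed trajectory to the posterior mean path and
to the blocks of the lower block-bidiagonal Cholesky factor R of the
precision.  Sampling uses the reparameterization g = m + R^{-T} zeta with
zeta standard normal, for which log q(g) is available in closed form:

    log q = sum log diag(R) - 0.5 ||zeta||^2 - (n/2) log(2 pi).

The Monte-Carlo evidence lower bound combines the control likelihood, the
initial-goal density, the goal-transition mixture densities and -log q;
penalties (exponential prior on the control noise, exponential prior on
component variances, hinge on off-screen modes) regularize training.

Goal-path convention per trial of T observed samples: row 0 is the
pre-movement goal (drawn from the initial GMM at the starting position),
row r >= 1 is the goal paired with observed position y[r-1].  Observed
control u_obs[r] = atanh(upsilon[r-1]) for r = 1..T-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_triangular

from . import game as game_mod
from .autodiff import Tensor, concat, custom_op, gather_rows
from .control import ControlParams, PROPORTIONAL_TAPS, invert_joystick
from .game import GameConfig, TrialTrajectory, check_termination, step_dynamics
from .goals import (GOALIE_DIMS, SHOOTER_DIMS, GoalPath, InitialGoalGMM,
                    PotentialModel, conditional_goal_sample)
from .nets import MLP, Adam
from .preprocess import gaussian_smooth, velocities

log = logging.getLogger("goaldyn")

GAUSS_CONST = 0.5 * np.log(2.0 * np.pi)
D_TOT = 3  # concatenated goal dimensions: shooter (x, y) + goalie (y)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class TrainConfig:
    """Hyperparameters of the two-phase variational training schedule."""

    lr: float = 1e-3
    warmup_epochs: int = 30          # taps frozen at pure proportional
    main_epochs: int = 500
    holdout_frac: float = 0.15
    n_mc_samples: int = 1
    rho: float = 1e5                 # exponential-prior weight on eps
    gamma: float = 0.1               # exponential-prior weight on 1/lambda
    hinge_margin: float = 1.5        # 1.5 x game half-extent
    hinge_weight: float = 100.0
    sigma: float = 1e-3
    K: int = 20
    K0: int = 20
    hidden: tuple = (128, 128)
    rec_hidden: tuple = (64, 64, 64)
    lag: int = 10
    lead: int = 5                    # future context of the posterior window
    tap_lr: float = 1e-3             # control taps move on a slower timescale
    batch_size: int = 64
    stop_tol: float = 0.01           # EMA percent-change stopping rule
    stop_patience: int = 5
    ema_halflife: float = 10.0
    variant: str = "nn_gmm"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.holdout_frac < 1.0):
            raise ValueError("holdout_frac must be in (0, 1)")
        for name in ("lr", "rho", "gamma", "hinge_margin", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk(cls, **kw) -> "TrainConfig":
        """Desk-scale preset: small mixtures and networks for CPU runs."""
        base = dict(K=5, K0=5, hidden=(32, 32), rec_hidden=(32, 32, 32),
                    warmup_epochs=30, main_epochs=100, batch_size=25, lr=5e-3)
        base.update(kw)
        return cls(**base)

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# per-trial preprocessing and packing
# --------------------------------------------------------------------------
@dataclass
class PreppedTrial:
    """A trial prepared for inference."""

    trial: TrialTrajectory
    y_s: np.ndarray        # (T, 3) smoothed positions
    u_obs: np.ndarray      # (T-1, 3) latent control recovered from joystick
    states: np.ndarray     # (T, d) state rows aligned with goal rows
    feat: np.ndarray       # (T, F) recognition features per goal row
    sat_frac: float = 0.0

    @property
    def n_goal_rows(self) -> int:
        return self.y_s.shape[0]


def recognition_features(y: np.ndarray, u_obs: np.ndarray, lag: int,
                         lead: int = 5) -> np.ndarray:
    """Windowed observations, one row per goal row.

    Each goal row r is centred on observed index max(r-1, 0) and spans
    ``lag`` samples of history plus ``lead`` samples of future context
    (the posterior is a smoother: the evidence for a goal is largely the
    movement it subsequently causes).  The window carries both positions
    and the recovered control signal u = atanh(upsilon) — the latter puts
    the per-step evidence on the scale the goal error lives on, which raw
    positions only encode through tiny adjacent differences.  Windows are
    clamped at the trial edges.
    """
    T = y.shape[0]
    centre = np.maximum(np.arange(T) - 1, 0)
    offs = np.arange(-lag, lead + 1)
    idx = np.clip(centre[:, None] + offs[None, :], 0, T - 1)
    # goal row r's own control is u_obs[r-1]; clamp into [0, T-2]
    idx_u = np.clip(centre[:, None] + offs[None, :], 0, T - 2)
    return np.concatenate([y[idx].reshape(T, -1),
                           u_obs[idx_u].reshape(T, -1)], axis=1)


def prep_trial(trial: TrialTrajectory, vmax, lag: int = 10, lead: int = 5,
               smooth: bool = True) -> PreppedTrial:
    """Recover latent control and build state/feature rows for one trial.

    States and recognition features use the raw positions: onscreen
    observations are essentially noiseless and the per-step differences
    carry the control signal, which heavy smoothing would remove.  The
    smoothed copy is kept for velocity estimates at the trial start and
    for downstream analyses.
    """
    y = trial.y
    y_s = gaussian_smooth(y) if smooth and y.shape[0] > 21 else y.astype(np.float64)
    u_obs, sat = invert_joystick(trial.upsilon)
    T = y.shape[0]
    vel = np.empty_like(y)
    vel[1:] = np.diff(y, axis=0)
    vel[0] = velocities(y_s)[0]  # padded estimate of the initial velocity
    cov = np.asarray([float(v) for v in trial.covariates.values()], dtype=np.float64)
    # state row r (r >= 1) is the state at observed index r-1
    pos_rows = y[np.maximum(np.arange(T) - 1, 0)]
    vel_rows = vel[np.maximum(np.arange(T) - 1, 0)]
    states = np.concatenate(
        [pos_rows, vel_rows, np.tile(cov, (T, 1))], axis=1)
    feat = recognition_features(y, u_obs, lag, lead)
    return PreppedTrial(trial, y_s, u_obs, states, feat, sat)


class PackedTrials:
    """Concatenation of prepared trials with the index arrays the ELBO
    graph needs (observation rows, transition rows, solver block indices)."""

    def __init__(self, trials: list[PreppedTrial]):
        if not trials:
            raise ValueError("empty batch")
        self.trials = trials
        self.n_trials = len(trials)
        lengths = np.array([p.n_goal_rows for p in trials])
        self.lengths = lengths
        self.starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        self.R = int(lengths.sum())

        self.feat = np.concatenate([p.feat for p in trials])
        self.states = np.concatenate([p.states for p in trials])
        # position paired with each goal row (goal dims == observed dims)
        self.pos = np.concatenate(
            [p.trial.y[np.maximum(np.arange(p.n_goal_rows) - 1, 0)] for p in trials])

        obs_rows, u_obs, u_prev, first_mask, row0 = [], [], [], [], []
        trans_rows, init_rows = [], []
        for p, s in zip(trials, self.starts):
            T = p.n_goal_rows
            r = np.arange(1, T)
            obs_rows.append(s + r)
            u_obs.append(p.u_obs)
            up = np.zeros((T - 1, 3))
            up[1:] = p.u_obs[:-1]
            u_prev.append(up)
            fm = np.zeros(T - 1)
            fm[0] = 1.0
            first_mask.append(fm)
            row0.append(np.full(T - 1, s))
            trans_rows.append(s + r)
            init_rows.append(s)
        self.obs_rows = np.concatenate(obs_rows)
        self.u_obs = np.concatenate(u_obs)
        self.u_prev = np.concatenate(u_prev)
        self.first_mask = np.concatenate(first_mask)[:, None]
        self.row0 = np.concatenate(row0)
        self.trans_rows = np.concatenate(trans_rows)
        self.init_rows = np.asarray(init_rows)
        self.mask2 = (self.obs_rows - self.starts[
            np.searchsorted(self.starts, self.obs_rows, side="right") - 1] >= 2
                      ).astype(np.float64)[:, None]
        self.n_obs = self.obs_rows.shape[0]

        # flat (i, j) indices of the Cholesky-factor entries, per trial
        self._solver_idx = []
        for p, s in zip(trials, self.starts):
            T = p.n_goal_rows
            n = T * D_TOT
            base = np.arange(T) * D_TOT
            di = np.stack([base + j for j in range(D_TOT)], axis=1)      # (T,3)
            # below-diagonal entries of each diagonal block: (1,0),(2,0),(2,1)
            li = np.stack([base + 1, base + 2, base + 2], axis=1)
            lj = np.stack([base + 0, base + 0, base + 1], axis=1)
            # sub-diagonal blocks: rows of block t, cols of block t-1, t>=1
            bi = (base[1:, None, None] + np.arange(D_TOT)[None, :, None]
                  + np.zeros(D_TOT, dtype=int)[None, None, :])
            bj = (base[:-1, None, None] + np.zeros(D_TOT, dtype=int)[None, :, None]
                  + np.arange(D_TOT)[None, None, :])
            self._solver_idx.append((n, di, (li, lj), (bi, bj)))


# --------------------------------------------------------------------------
# recognition model
# --------------------------------------------------------------------------
class RecognitionModel:
    """Structured Gaussian posterior over concatenated goal paths.

    ``mean_net`` produces the posterior mean as an offset from the current
    position (so the initial posterior sits near the trajectory);
    ``diag_net`` produces, per time step, 3 log-diagonal entries and 3
    below-diagonal entries of the diagonal Cholesky block; ``offdiag_net``
    produces the 9 entries of the sub-diagonal block.
    """

    def __init__(self, d_feat: int, hidden=(64, 64, 64), lag: int = 10,
                 lead: int = 5, sigma: float = 1e-3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.lag, self.lead = lag, lead
        self.d_feat = d_feat
        self.sigma = float(sigma)
        log_r = 0.5 * np.log(2.0) - np.log(sigma)  # ~ sqrt of prior precision
        # zero-init mean head: the posterior mean starts exactly at the
        # observed positions, the smoothest path consistent with the data.
        # The linear skip lets each goal dimension read its control
        # evidence directly, without competing for shared hidden units.
        self.mean_net = MLP([d_feat, *hidden, D_TOT], rng, out_weight_scale=0.0)
        # the skip starts at the proportional-control inversion
        # g = y + atanh(upsilon): the exact goal estimate under the
        # warm-start controller, so control residuals begin near zero
        skip = np.zeros((d_feat, D_TOT))
        w_len = d_feat // (2 * D_TOT)
        for j in range(D_TOT):
            skip[w_len * D_TOT + lag * D_TOT + j, j] = 1.0
        self.mean_skip = Tensor(skip, requires_grad=True)
        # sub-diagonal blocks start at the kinetic-prior structure
        # (B = -beta / D with D = sqrt(2 beta)), so the posterior begins
        # with the random-walk temporal correlations the prior implies
        beta = sigma ** -2
        off_bias = np.zeros(D_TOT * D_TOT)
        off_bias[[0, 4, 8]] = -beta / np.exp(0.5 * np.log(2.0) - np.log(sigma))
        self.diag_net = MLP([d_feat, *hidden, 2 * D_TOT], rng,
                            out_weight_scale=0.1,
                            out_bias=[log_r] * D_TOT + [0.0] * D_TOT)
        self.offdiag_net = MLP([d_feat, *hidden, D_TOT * D_TOT], rng,
                               out_weight_scale=0.01, out_bias=off_bias)

    @property
    def params(self):
        return [self.mean_skip] + self.mean_net.params + \
            self.diag_net.params + self.offdiag_net.params

    @property
    def mean_params(self):
        return [self.mean_skip] + self.mean_net.params

    @property
    def precision_params(self):
        return self.diag_net.params + self.offdiag_net.params

    def blocks(self, packed: PackedTrials):
        """Posterior mean and Cholesky-factor entries for a packed batch."""
        feat = Tensor(packed.feat)
        m = Tensor(packed.pos) + feat @ self.mean_skip + self.mean_net(feat)
        dd = self.diag_net(feat)
        dlog = dd[:, 0:D_TOT]
        dlow = dd[:, D_TOT:2 * D_TOT]
        off = self.offdiag_net(feat)
        return m, dlog, dlow, off

    def state_dict(self) -> dict:
        return {"lag": self.lag, "lead": self.lead, "d_feat": self.d_feat,
                "sigma": self.sigma, "mean_skip": self.mean_skip.data,
                "mean": self.mean_net.state_dict(),
                "diag": self.diag_net.state_dict(),
                "off": self.offdiag_net.state_dict()}

    @classmethod
    def from_state(cls, d: dict) -> "RecognitionModel":
        obj = cls.__new__(cls)
        obj.lag, obj.d_feat = int(d["lag"]), int(d["d_feat"])
        obj.lead = int(d.get("lead", 0))
        obj.sigma = float(d["sigma"])
        obj.mean_net = MLP.from_state(d["mean"])
        obj.mean_skip = Tensor(np.asarray(d["mean_skip"]), requires_grad=True)
        obj.diag_net = MLP.from_state(d["diag"])
        obj.offdiag_net = MLP.from_state(d["off"])
        return obj


class FixedRecognition:
    """Posterior with directly supplied mean and Cholesky blocks.

    Used for conjugate-oracle tests where the exact posterior is known in
    closed form.  ``dlog`` holds log-diagonal entries.
    """

    lag = 0
    lead = 0
    params: list = []

    def __init__(self, m, dlog, dlow, off):
        self.m = np.asarray(m, dtype=np.float64)
        self.dlog = np.asarray(dlog, dtype=np.float64)
        self.dlow = np.asarray(dlow, dtype=np.float64)
        self.off = np.asarray(off, dtype=np.float64)

    def blocks(self, packed: PackedTrials):
        return (Tensor(self.m), Tensor(self.dlog),
                Tensor(self.dlow), Tensor(self.off))


def _assemble_R(packed: PackedTrials, k: int, dlog, dlow, off) -> np.ndarray:
    """Dense lower-triangular Cholesky factor for trial k of the batch."""
    s, T = packed.starts[k], packed.lengths[k]
    n, di, (li, lj), (bi, bj) = packed._solver_idx[k]
    R = np.zeros((n, n))
    sl = slice(s, s + T)
    R[di, di] = np.exp(dlog[sl])
    R[li, lj] = dlow[sl]
    R[bi, bj] = off[sl][1:].reshape(T - 1, D_TOT, D_TOT)
    return R


def bidiag_solve_T(packed: PackedTrials, dlog: Tensor, dlow: Tensor,
                   off: Tensor, zeta: np.ndarray) -> Tensor:
    """x = R^{-T} zeta for every trial in the batch (custom autodiff op).

    ``dlog``/``dlow``/``off`` are (R, 3)/(R, 3)/(R, 9) Tensors of
    Cholesky-factor entries; ``zeta`` is a constant (R, 3) noise array.
    Raises if any diagonal entry is non-finite (non-PD blocks).
    """
    if not np.all(np.isfinite(dlog.data)):
        bad = np.where(~np.isfinite(dlog.data))[0][:1]
        raise FloatingPointError(f"non-finite Cholesky diagonal at row {bad}")
    xs, caches = [], []
    for k in range(packed.n_trials):
        s, T = packed.starts[k], packed.lengths[k]
        R = _assemble_R(packed, k, dlog.data, dlow.data, off.data)
        z = zeta[s:s + T].ravel()
        x = solve_triangular(R.T, z, lower=False)
        xs.append(x.reshape(T, D_TOT))
        caches.append((R, x))
    value = np.concatenate(xs)

    def vjp(gbar):
        gd = np.zeros_like(dlog.data)
        gl = np.zeros_like(dlow.data)
        go = np.zeros_like(off.data)
        for k in range(packed.n_trials):
            s, T = packed.starts[k], packed.lengths[k]
            n, di, (li, lj), (bi, bj) = packed._solver_idx[k]
            R, x = caches[k]
            w = solve_triangular(R, gbar[s:s + T].ravel(), lower=True)
            # dJ/dR[i, j] = -x[i] w[j] at the stored sparsity pattern
            sl = slice(s, s + T)
            gd[sl] += -x[di] * w[di] * np.exp(dlog.data[sl])
            gl[sl] += -x[li] * w[lj]
            go[s + 1:s + T] += (-x[bi] * w[bj]).reshape(T - 1, D_TOT * D_TOT)
        return gd, gl, go

    return custom_op((dlog, dlow, off), value, vjp)


# --------------------------------------------------------------------------
# generative parameters
# --------------------------------------------------------------------------
class GenerativeModel:
    """Trainable generative parameters: control taps/noise + potentials."""

    def __init__(self, d_state: int, cfg: TrainConfig,
                 rng: np.random.Generator | None = None,
                 shooter: PotentialModel | None = None,
                 goalie: PotentialModel | None = None):
        rng = rng or np.random.default_rng(0)
        self.taps = Tensor(np.tile(PROPORTIONAL_TAPS, (3, 1)), requires_grad=True)
        # start in the low-control-noise regime the model asserts (eps << 1)
        self.log_eps = Tensor(np.log(np.full(3, 0.02)), requires_grad=True)
        self.sigma = cfg.sigma
        self.shooter = shooter or PotentialModel(
            cfg.variant, D=2, d_in=d_state, K=cfg.K, hidden=cfg.hidden,
            sigma=cfg.sigma, rng=rng, K0=cfg.K0)
        self.goalie = goalie or PotentialModel(
            cfg.variant, D=1, d_in=d_state, K=cfg.K, hidden=cfg.hidden,
            sigma=cfg.sigma, rng=rng, K0=cfg.K0)

    @property
    def params_no_taps(self):
        return [self.log_eps] + self.shooter.params + self.goalie.params

    @property
    def control(self) -> ControlParams:
        return ControlParams(taps=self.taps.data.copy(),
                             eps=np.exp(self.log_eps.data))

    def state_dict(self) -> dict:
        return {"taps": self.taps.data, "log_eps": self.log_eps.data,
                "sigma": self.sigma, "shooter": self.shooter.state_dict(),
                "goalie": self.goalie.state_dict()}

    @classmethod
    def from_state(cls, d: dict) -> "GenerativeModel":
        obj = cls.__new__(cls)
        obj.taps = Tensor(np.asarray(d["taps"]), requires_grad=True)
        obj.log_eps = Tensor(np.asarray(d["log_eps"]), requires_grad=True)
        obj.sigma = float(d["sigma"])
        obj.shooter = PotentialModel.from_state(d["shooter"])
        obj.goalie = PotentialModel.from_state(d["goalie"])
        return obj


# --------------------------------------------------------------------------
# the ELBO graph
# --------------------------------------------------------------------------
def _log_joint(packed: PackedTrials, gen: GenerativeModel, g: Tensor) -> Tensor:
    """log p(u_obs, g) summed over a packed batch, as a graph Tensor."""
    pos = Tensor(packed.pos)
    e = g - pos
    taps = gen.taps
    L0, L1, L2 = taps[:, 0], taps[:, 1], taps[:, 2]
    e_t = gather_rows(e, packed.obs_rows)
    e_1 = gather_rows(e, packed.obs_rows - 1)
    e_2 = gather_rows(e, np.maximum(packed.obs_rows - 2, 0)) * Tensor(packed.mask2)
    du = e_t * L0 + e_1 * L1 + e_2 * L2
    # previous control: observed u for r >= 2; the bootstrap u_0 = L0 e_0
    # (a function of the latent pre-goal) for the first observation
    u_prev = Tensor(packed.u_prev) + \
        gather_rows(e, packed.row0) * L0 * Tensor(packed.first_mask)
    u_star = u_prev + du
    eps = gen.log_eps.exp()
    z = (Tensor(packed.u_obs) - u_star) / eps
    ll_control = (z * z).sum() * (-0.5) \
        - gen.log_eps.sum() * packed.n_obs - packed.n_obs * 3 * GAUSS_CONST

    # initial goals
    g0 = gather_rows(g, packed.init_rows)
    ll_init = gen.shooter.init_gmm.logpdf_t(g0[:, SHOOTER_DIMS]).sum() + \
        gen.goalie.init_gmm.logpdf_t(g0[:, GOALIE_DIMS]).sum()

    # transitions
    states = Tensor(packed.states[packed.trans_rows])
    g_t = gather_rows(g, packed.trans_rows)
    g_p = gather_rows(g, packed.trans_rows - 1)
    ll_trans = Tensor(0.0)
    for pot, dims in ((gen.shooter, SHOOTER_DIMS), (gen.goalie, GOALIE_DIMS)):
        log_w, mu_f, lam_f = pot.gmm_params_t(states)
        n, D = packed.trans_rows.shape[0], pot.D
        K = log_w.shape[1]
        mu = mu_f.reshape(n, K, D)
        lam = lam_f.reshape(n, K, D)
        one_p = lam + 1.0
        mean = (g_p[:, dims].reshape(n, 1, D) + lam * mu) / one_p
        var = one_p ** -1.0 * pot.sigma ** 2
        diff = g_t[:, dims].reshape(n, 1, D) - mean
        lp = (var.log() * (-0.5) - diff * diff / var * 0.5 - GAUSS_CONST).sum(axis=2)
        ll_trans = ll_trans + (lp + log_w).logsumexp(axis=1).sum()
    return ll_control + ll_init + ll_trans


def _penalties(packed: PackedTrials, gen: GenerativeModel,
               cfg: TrainConfig, pen_scale: float) -> Tensor:
    """Regularization terms added to the ELBO (all <= 0)."""
    eps = gen.log_eps.exp()
    pen = eps.sum() * (-cfg.rho * pen_scale)
    states = Tensor(packed.states[packed.trans_rows])
    for pot in (gen.shooter, gen.goalie):
        if pot.variant == "scripted":
            continue
        _, mu_f, lam_f = pot.gmm_params_t(states)
        pen = pen + (lam_f ** -1.0).sum() * (-cfg.gamma)
        hinge = (mu_f.abs() - cfg.hinge_margin).relu()
        pen = pen + hinge.sum() * (-cfg.hinge_weight)
    return pen


def regularization_penalty(gen: GenerativeModel, lam: np.ndarray,
                           mu: np.ndarray, cfg: TrainConfig) -> float:
    """Closed-form penalty value for given mixture parameters (for
    diagnostics and tests; matches the graph terms with pen_scale = 1)."""
    eps = np.exp(gen.log_eps.data)
    pen = -cfg.rho * eps.sum()
    pen += -cfg.gamma * np.sum(1.0 / lam)
    pen += -cfg.hinge_weight * np.sum(np.maximum(np.abs(mu) - cfg.hinge_margin, 0.0))
    return float(pen)


def _draw_sample(packed: PackedTrials, rec, rng: np.random.Generator):
    """One reparameterized posterior sample over a packed batch."""
    m, dlog, dlow, off = rec.blocks(packed)
    zeta = rng.standard_normal((packed.R, D_TOT))
    x = bidiag_solve_T(packed, dlog, dlow, off, zeta)
    g = m + x
    logq = dlog.sum() - 0.5 * float(np.sum(zeta ** 2)) \
        - packed.R * D_TOT * GAUSS_CONST
    return g, logq


def elbo_estimate(trials, gen: GenerativeModel, rec, n_mc: int,
                  rng: np.random.Generator,
                  packed: PackedTrials | None = None) -> float:
    """Monte-Carlo ELBO per trial (no penalties) for a list of prepared
    trials (or an already packed batch)."""
    packed = packed or PackedTrials(list(trials))
    total = 0.0
    for _ in range(n_mc):
        g, logq = _draw_sample(packed, rec, rng)
        total += float(_log_joint(packed, gen, g).data) - float(logq.data)
    return total / (n_mc * packed.n_trials)


def posterior_sample(trial, rec, rng: np.random.Generator, n: int = 1,
                     vmax=None, prepped: PreppedTrial | None = None):
    """Draw n goal-path samples + exact log q values for one trial."""
    if prepped is None:
        if vmax is None:
            raise ValueError("need vmax to preprocess the trial")
        prepped = prep_trial(trial, vmax, lag=rec.lag, lead=rec.lead)
    packed = PackedTrials([prepped])
    paths, logqs = [], []
    for _ in range(n):
        g, logq = _draw_sample(packed, rec, rng)
        paths.append(GoalPath(g.data.copy(), provenance="posterior_sample"))
        logqs.append(float(logq.data))
    return paths, np.asarray(logqs)


def posterior_mean_path(prepped: PreppedTrial, rec) -> np.ndarray:
    """Posterior mean goal path (T, 3) for one prepared trial."""
    packed = PackedTrials([prepped])
    m, _, _, _ = rec.blocks(packed)
    return m.data.copy()


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------
@dataclass
class FittedModel:
    """Generative + recognition parameters plus the training history."""

    gen: GenerativeModel
    rec: RecognitionModel
    history: list = field(default_factory=list)
    cfg: TrainConfig | None = None
    game: GameConfig | None = None
    vmax: np.ndarray | None = None

    @property
    def control(self) -> ControlParams:
        return self.gen.control

    @property
    def potentials(self) -> dict:
        return {"shooter": self.gen.shooter, "goalie": self.gen.goalie}


def estimate_vmax(trials) -> np.ndarray:
    """Per-dimension max |dy| over a session's trials."""
    return np.max([np.max(np.abs(np.diff(t.y, axis=0)), axis=0) for t in trials],
                  axis=0)


def holdout_split(n: int, frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_hold = max(1, int(round(frac * n)))
    return idx[n_hold:], idx[:n_hold]


def fit(trials, cfg: TrainConfig, game: GameConfig | None = None,
        callback=None) -> FittedModel:
    """Two-phase variational training.

    Phase 1 (``warmup_epochs``): control taps frozen at pure proportional
    (1, -1, 0).  Phase 2 (``main_epochs``): taps free; stops early when
    the percent change of an exponential moving average of the per-epoch
    training ELBO stays below ``stop_tol`` for ``stop_patience`` epochs.
    """
    rng = np.random.default_rng(cfg.seed)
    vmax = estimate_vmax(trials) if game is None else game.vmax_arr
    prepped = [prep_trial(t, vmax, lag=cfg.lag, lead=cfg.lead) for t in trials]
    d_state = prepped[0].states.shape[1]

    train_idx, hold_idx = holdout_split(len(prepped), cfg.holdout_frac, rng)
    train = [prepped[i] for i in train_idx]
    hold = [prepped[i] for i in hold_idx]
    batches = [PackedTrials(train[i:i + cfg.batch_size])
               for i in range(0, len(train), cfg.batch_size)]
    hold_packed = PackedTrials(hold) if hold else None
    n_total = len(train)

    gen = GenerativeModel(d_state, cfg, rng)
    rec = RecognitionModel(prepped[0].feat.shape[1], cfg.rec_hidden,
                           cfg.lag, cfg.lead, cfg.sigma, rng)
    # the posterior mean stays frozen at its control-inversion
    # initialization through warmup, so the potential first learns to
    # explain those goal paths before the posterior is free to drift
    opt = Adam(gen.params_no_taps + rec.precision_params, lr=cfg.lr)
    opt_taps = None
    opt_mean = None

    history = []
    ema = None
    alpha = 1.0 - 0.5 ** (1.0 / cfg.ema_halflife)
    stall = 0
    checkpoint = None

    n_epochs = cfg.warmup_epochs + cfg.main_epochs
    for epoch in range(n_epochs):
        if epoch == cfg.warmup_epochs and opt_taps is None:
            opt_taps = Adam([gen.taps], lr=cfg.tap_lr)
            # the mean path moves on the taps' slow timescale: both ride
            # the weakly identified control-gain direction
            opt_mean = Adam(rec.mean_params, lr=cfg.tap_lr)
        in_warmup = epoch < cfg.warmup_epochs
        epoch_elbo, n_ok = 0.0, 0
        for packed in batches:
            terms = []
            for _ in range(cfg.n_mc_samples):
                g, logq = _draw_sample(packed, rec, rng)
                terms.append(_log_joint(packed, gen, g) - logq)
            pen_scale = packed.n_trials / n_total
            obj = terms[0]
            for t in terms[1:]:
                obj = obj + t
            obj = obj * (1.0 / cfg.n_mc_samples) + \
                _penalties(packed, gen, cfg, pen_scale)
            val = float(obj.data)
            if not np.isfinite(val):
                log.warning("non-finite objective at epoch %d; step skipped",
                            epoch)
                continue
            opt.zero_grad()
            if opt_taps is not None:
                opt_taps.zero_grad()
                opt_mean.zero_grad()
            scaled = obj * (1.0 / packed.n_trials)
            scaled.backward()
            opt.step()
            if opt_taps is not None and not in_warmup:
                opt_taps.step()
                opt_mean.step()
            epoch_elbo += val / packed.n_trials
            n_ok += 1
        if n_ok == 0:
            log.error("epoch %d diverged; restoring last checkpoint", epoch)
            if checkpoint is not None:
                gen = GenerativeModel.from_state(checkpoint[0])
                rec = RecognitionModel.from_state(checkpoint[1])
            break
        per_trial = epoch_elbo / n_ok
        hold_elbo = (elbo_estimate(None, gen, rec, 1, rng, packed=hold_packed)
                     if hold_packed is not None else np.nan)
        history.append({"epoch": epoch, "phase": 1 if in_warmup else 2,
                        "train_elbo": per_trial, "holdout_elbo": hold_elbo,
                        "taps": gen.taps.data.copy(),
                        "eps": np.exp(gen.log_eps.data)})
        checkpoint = (gen.state_dict(), rec.state_dict())
        if callback is not None:
            callback(history[-1])

        prev = ema
        ema = per_trial if ema is None else (1 - alpha) * ema + alpha * per_trial
        if not in_warmup and prev is not None and cfg.stop_tol > 0:
            pct = abs(ema - prev) / max(abs(prev), 1e-12)
            stall = stall + 1 if pct < cfg.stop_tol else 0
            if stall >= cfg.stop_patience:
                log.info("early stop at epoch %d (EMA change < %.2f%%)",
                         epoch, 100 * cfg.stop_tol)
                break
    return FittedModel(gen, rec, history, cfg, game, vmax)


# --------------------------------------------------------------------------
# trial completion / counterfactual rollouts
# --------------------------------------------------------------------------
def complete_trial(prefix: TrialTrajectory, model: FittedModel, n: int,
                   t0: int, rng: np.random.Generator,
                   clamp: dict | None = None, max_steps: int = 600,
                   eps_override: np.ndarray | None = None):
    """Complete a trial from step t0, optionally clamping initial goals.

    ``clamp`` maps agent name ('shooter' or 'goalie') to the goal value
    imposed at the first completion step (goals move normally afterwards).
    Returns ``(trajectories, goal_paths)`` lists of length n.
    """
    if t0 < 3:
        raise ValueError("need t0 >= 3 for control history")
    clamp = clamp or {}
    for agent, val in clamp.items():
        v = np.atleast_1d(np.asarray(val, dtype=np.float64))
        if np.any(np.abs(v) > 1.5):
            raise ValueError(f"clamp for {agent} outside 1.5x game area")
    game = model.game or GameConfig()
    vmax = model.vmax if model.vmax is not None else game.vmax_arr
    control = model.control
    eps = eps_override if eps_override is not None else control.eps
    cov = prefix.covariates
    cov_arr = np.asarray([float(v) for v in cov.values()], dtype=np.float64)

    sub = TrialTrajectory(prefix.trial_id, prefix.y[:t0 + 1],
                          prefix.upsilon[:t0], game_mod.TRUNCATED,
                          dict(cov), prefix.session_id)
    prepped = prep_trial(sub, vmax, lag=model.rec.lag, lead=model.rec.lead)
    u_obs = prepped.u_obs

    completions, goal_paths = [], []
    for i in range(n):
        paths, _ = posterior_sample(sub, model.rec, rng, n=1, prepped=prepped)
        gpath = paths[0].g                      # rows 0..t0 (goal row t0 <-> y[t0-1])
        g_prev2, g_prev = gpath[-2].copy(), gpath[-1].copy()
        y = [row.copy() for row in prefix.y[:t0 + 1]]
        ups = [row.copy() for row in prefix.upsilon[:t0]]
        gs = [g_prev.copy()]
        u_prev = u_obs[-1].copy()
        e_prev = g_prev - prefix.y[t0 - 1]
        e_prev2 = g_prev2 - prefix.y[max(t0 - 2, 0)]
        idle = 0.0
        outcome = game_mod.TRUNCATED
        first = True
        while len(ups) - t0 < max_steps:
            pos = y[-1]
            vel = (y[-1] - y[-2]) / 1.0
            state = np.concatenate([pos, vel, cov_arr])[None, :]
            g = np.empty(3)
            for agent, pot, dims in (("shooter", model.gen.shooter, SHOOTER_DIMS),
                                     ("goalie", model.gen.goalie, GOALIE_DIMS)):
                if first and agent in clamp:
                    g[dims] = np.atleast_1d(np.asarray(clamp[agent], dtype=np.float64))
                else:
                    w, mu, lam = pot.gmm_params_np(state)
                    g[dims], _ = conditional_goal_sample(
                        g_prev[dims], (w[0], mu[0], lam[0]), pot.sigma, rng)
            e = g - pos
            du = (control.taps[:, 0] * e + control.taps[:, 1] * e_prev
                  + control.taps[:, 2] * e_prev2)
            u = u_prev + du + eps * rng.standard_normal(3)
            upsilon = np.tanh(u)
            y.append(step_dynamics(pos, upsilon, game))
            ups.append(upsilon)
            gs.append(g.copy())
            if np.all(upsilon[:2] == 0.0):
                idle += game.dt
            elif game.rolling_timeout:
                idle = 0.0
            res = check_termination(y[-1], idle, game)
            e_prev2, e_prev, g_prev, u_prev, first = e_prev, e, g, u, False
            if res != game_mod.ONGOING:
                outcome = res
                break
        completions.append(TrialTrajectory(prefix.trial_id, np.array(y),
                                           np.array(ups), outcome, dict(cov),
                                           prefix.session_id))
        goal_paths.append(GoalPath(np.array(gs), provenance="clamped"
                                   if clamp else "posterior_sample"))
    return completions, goal_paths
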