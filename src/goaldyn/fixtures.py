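"""Ground-truth synthetic data: scripted agents with known control taps,
closed-form potentials and recorded latent goals.

The scenarios are closed-form stand-ins for the neural-network potential,
so parameter-recovery targets are unambiguous:

* shooter ``straight_shot`` — one component at the goal line whose
  vertical position amplifies the puck's current heading, committing the
  shooter to an up/centre/down run decided by its initial goal draw;
* shooter ``two_mode_feint`` — two components at the goal line's top and
  bottom whose weights flip against the goalie's vertical velocity (when
  the goalie commits upward the lower mode dominates), giving genuinely
  bimodal goal transitions;
* shooter ``mixed`` — straight mode plus the two feint modes, with the
  feint weight increasing with the session-trend covariate (injected
  complexity drift across sessions);
* goalie ``tracker`` — one component at the puck's vertical position with
  strong pull; ``lagged_tracker`` — the same with weak pull (sluggish).

All scenario parameter maps take the full state row
(positions, velocities, session trend, condition flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .control import ControlParams
from .game import (GameConfig, ONGOING, TRUNCATED, TrialTrajectory,
                   check_termination, initial_state, step_dynamics)
from .goals import (GOALIE_DIMS, SHOOTER_DIMS, GoalPath, InitialGoalGMM,
                    PotentialModel, conditional_goal_sample)

__all__ = ["FixtureConfig", "LabeledDataset", "scenario_potential",
           "make_truth_models", "generate_dataset", "parameter_recovery_report"]

SHOOTER_SCENARIOS = ("two_mode_feint", "straight_shot", "mixed")
GOALIE_SCENARIOS = ("tracker", "lagged_tracker")

# state-column layout produced by inference.prep_trial / the rollout
COL_XP, COL_YP, COL_YG, COL_VXP, COL_VYP, COL_VYG, COL_TREND = range(7)

FEINT_AMPLITUDE = 0.6
FEINT_SHARPNESS = 4.0       # weight-logit gain on goalie pursuit velocity
FEINT_COMMIT = 2.0          # weight-logit gain on the puck's own heading
FEINT_LAMBDA = 0.05
STRAIGHT_LAMBDA = (0.5, 2.0)
TRACKER_LAMBDA = 2.0
LAGGED_LAMBDA = 0.05
TRACKER_LOOKAHEAD = 8.0     # steps of velocity extrapolation in the pursuit aim
TARGET_X = 1.0        # shooters aim past the goal line, at the screen edge
FEINT_PROX_X = 0.0    # puck x at which the feint response is half-engaged


@dataclass
class FixtureConfig:
    """Ground-truth generator settings (defaults are the study conditions)."""

    n_trials: int = 500
    max_steps: int = 300
    seed: int = 0
    true_kappas: tuple = (1.2, 1.2, 0.8)   # proportional gain per dimension
    true_eps: tuple = (0.003, 0.003, 0.003)  # minimal-noise regime (eps << 1)
    true_sigma: float = 0.015
    shooter_scenario: str = "two_mode_feint"
    goalie_scenario: str = "tracker"
    n_sessions: int = 10
    complexity_drift: float = 2.0          # feint-logit gain on session trend
    game: GameConfig = field(default_factory=GameConfig)

    def __post_init__(self):
        if self.shooter_scenario not in SHOOTER_SCENARIOS:
            raise ValueError(f"unknown shooter scenario {self.shooter_scenario!r}")
        if self.goalie_scenario not in GOALIE_SCENARIOS:
            raise ValueError(f"unknown goalie scenario {self.goalie_scenario!r}")

    @property
    def true_taps(self) -> np.ndarray:
        return np.outer(np.asarray(self.true_kappas, dtype=np.float64),
                        np.array([1.0, -1.0, 0.0]))

    @property
    def control(self) -> ControlParams:
        # eps floor keeps ControlParams valid for noiseless replay datasets
        eps = np.maximum(np.asarray(self.true_eps, dtype=np.float64), 1e-300)
        return ControlParams(taps=self.true_taps, eps=eps)


@dataclass
class LabeledDataset:
    """Fixture trials with their recorded ground-truth goal paths."""

    trials: list
    goals: list                 # GoalPath per trial, rows aligned with inference
    truth: FixtureConfig

    def __len__(self):
        return len(self.trials)


# --------------------------------------------------------------------------
# closed-form potentials
# --------------------------------------------------------------------------
def scenario_potential(states: np.ndarray, scenario: str,
                       game: GameConfig | None = None,
                       drift_gain: float = 0.0):
    """Mixture parameters (w, mu, lam) for a batch of state rows.

    Returns arrays (n, K), (n, K, D), (n, K, D).
    """
    game = game or GameConfig()
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    n = states.shape[0]
    gx = TARGET_X

    if scenario in ("tracker", "lagged_tracker"):
        lam_val = TRACKER_LAMBDA if scenario == "tracker" else LAGGED_LAMBDA
        # anticipatory pursuit: aim where the puck is heading
        mu = (states[:, COL_YP]
              + TRACKER_LOOKAHEAD * states[:, COL_VYP]).reshape(n, 1, 1)
        return np.ones((n, 1)), mu, np.full((n, 1, 1), lam_val)

    if scenario == "straight_shot":
        target = 0.7 * np.tanh(3.0 * (states[:, COL_YP] + 10.0 * states[:, COL_VYP]))
        mu = np.stack([np.full(n, gx), target], axis=1).reshape(n, 1, 2)
        lam = np.tile(np.asarray(STRAIGHT_LAMBDA).reshape(1, 1, 2), (n, 1, 1))
        return np.ones((n, 1)), mu, lam

    if scenario == "two_mode_feint":
        vdir = np.clip(states[:, COL_VYG] / game.vmax_arr[2], -1.0, 1.0)
        # self-reinforcing commitment to the current heading, overridden —
        # increasingly so as the puck nears the bar — when the goalie
        # commits to a pursuit direction; the vertical pull also tightens
        # with proximity (players decide at the decision point)
        head = np.tanh(3.0 * (states[:, COL_YP] + 10.0 * states[:, COL_VYP]))
        prox = 1.0 / (1.0 + np.exp(-6.0 * (states[:, COL_XP] - FEINT_PROX_X)))
        top = FEINT_COMMIT * head \
            - FEINT_SHARPNESS * (0.3 + 0.7 * prox) * vdir
        logits = np.stack([top, -top], axis=1)
        w = softmax(logits, axis=1)
        mu = np.empty((n, 2, 2))
        mu[:, 0] = (gx, FEINT_AMPLITUDE)     # top mode
        mu[:, 1] = (gx, -FEINT_AMPLITUDE)    # bottom mode
        lam = np.full((n, 2, 2), FEINT_LAMBDA)
        lam[:, :, 0] = STRAIGHT_LAMBDA[0]
        return w, mu, lam

    if scenario == "mixed":
        vdir = np.clip(states[:, COL_VYG] / game.vmax_arr[2], -1.0, 1.0)
        trend = states[:, COL_TREND] if states.shape[1] > COL_TREND else np.zeros(n)
        head = np.tanh(3.0 * (states[:, COL_YP] + 10.0 * states[:, COL_VYP]))
        prox = 1.0 / (1.0 + np.exp(-6.0 * (states[:, COL_XP] - FEINT_PROX_X)))
        feint_bonus = drift_gain * trend - 1.0
        top = FEINT_COMMIT * head \
            - FEINT_SHARPNESS * (0.3 + 0.7 * prox) * vdir
        logits = np.stack([np.zeros(n), feint_bonus + top,
                           feint_bonus - top], axis=1)
        w = softmax(logits, axis=1)
        target = 0.7 * np.tanh(3.0 * (states[:, COL_YP] + 10.0 * states[:, COL_VYP]))
        mu = np.empty((n, 3, 2))
        mu[:, 0, 0] = gx
        mu[:, 0, 1] = target
        mu[:, 1] = (gx, FEINT_AMPLITUDE)
        mu[:, 2] = (gx, -FEINT_AMPLITUDE)
        lam = np.full((n, 3, 2), FEINT_LAMBDA)
        lam[:, 0] = STRAIGHT_LAMBDA
        lam[:, 1:, 0] = STRAIGHT_LAMBDA[0]
        return w, mu, lam

    raise ValueError(f"unknown scenario {scenario!r}")


def make_truth_models(cfg: FixtureConfig):
    """Scripted shooter/goalie PotentialModels realizing the scenarios."""
    rng = np.random.default_rng(cfg.seed)

    def shooter_fn(states):
        return scenario_potential(states, cfg.shooter_scenario, cfg.game,
                                  cfg.complexity_drift)

    def goalie_fn(states):
        return scenario_potential(states, cfg.goalie_scenario, cfg.game)

    shooter_init = InitialGoalGMM(
        D=2, K0=3, rng=rng,
        means=np.array([[-0.2, -0.4], [-0.2, 0.0], [-0.2, 0.4]]),
        log_sigma=np.log(0.15))
    goalie_init = InitialGoalGMM(D=1, K0=1, rng=rng,
                                 means=np.zeros((1, 1)),
                                 log_sigma=np.log(0.1))
    shooter = PotentialModel("scripted", D=2, d_in=8, sigma=cfg.true_sigma,
                             fn=shooter_fn, init_gmm=shooter_init)
    goalie = PotentialModel("scripted", D=1, d_in=8, sigma=cfg.true_sigma,
                            fn=goalie_fn, init_gmm=goalie_init)
    return shooter, goalie


# --------------------------------------------------------------------------
# generative rollout
# --------------------------------------------------------------------------
def _rollout(trial_id: int, cfg: FixtureConfig, shooter: PotentialModel,
             goalie: PotentialModel, control: ControlParams,
             covariates: dict, rng: np.random.Generator):
    """Full generative rollout: bootstrap, then goal/control/physics loop."""
    game = cfg.game
    eps = control.eps
    noise = bool(np.any(eps > 0))
    y0 = initial_state(game)
    cov_arr = np.asarray(list(covariates.values()), dtype=np.float64)

    # five-step bootstrap (goals g0, g1 drawn at the initial state)
    from .goals import bootstrap_initial
    g0, g1, u0, u1, e_hist = bootstrap_initial(
        y0, shooter, goalie, control, rng, covariates, noise=noise)
    y = [y0]
    ups = []
    gs = [g0, g1]
    ks = [-1, -1]
    e1, e0 = e_hist[0], e_hist[1]
    e_prev, e_prev2 = e1, e0
    u_prev = u1
    ups.append(np.tanh(u1))
    y.append(step_dynamics(y0, ups[-1], game))
    idle = 0.0
    outcome = TRUNCATED

    for _ in range(cfg.max_steps - 1):
        res = check_termination(y[-1], idle, game)
        if res != ONGOING:
            outcome = res
            break
        pos = y[-1]
        vel = y[-1] - y[-2]
        state = np.concatenate([pos, vel, cov_arr])[None, :]
        g = np.empty(3)
        kk = np.empty(2, dtype=int)
        for i, (pot, dims) in enumerate(((shooter, SHOOTER_DIMS),
                                         (goalie, GOALIE_DIMS))):
            w, mu, lam = pot.gmm_params_np(state)
            g[dims], kk[i] = conditional_goal_sample(
                gs[-1][dims], (w[0], mu[0], lam[0]), pot.sigma, rng)
        e = g - pos
        du = (control.taps[:, 0] * e + control.taps[:, 1] * e_prev
              + control.taps[:, 2] * e_prev2)
        u = u_prev + du
        if noise:
            u = u + eps * rng.standard_normal(3)
        upsilon = np.tanh(u)
        y.append(step_dynamics(pos, upsilon, game))
        ups.append(upsilon)
        gs.append(g)
        ks.append(kk[0])
        if np.all(upsilon[:2] == 0.0):
            idle += game.dt
        elif game.rolling_timeout:
            idle = 0.0
        e_prev2, e_prev, u_prev = e_prev, e, u
    else:
        outcome = TRUNCATED
    if outcome == TRUNCATED:
        res = check_termination(y[-1], idle, game)
        if res != ONGOING:
            outcome = res

    trial = TrialTrajectory(trial_id, np.array(y), np.array(ups), outcome,
                            dict(covariates))
    path = GoalPath(np.array(gs), component_ids=np.array(ks),
                    provenance="generated")
    return trial, path


def generate_dataset(cfg: FixtureConfig) -> LabeledDataset:
    """Generate a seeded, bitwise-reproducible labelled dataset."""
    shooter, goalie = make_truth_models(cfg)
    control = cfg.control
    trials, paths = [], []
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trials)
    for i in range(cfg.n_trials):
        session = i * cfg.n_sessions // cfg.n_trials
        trend = session / max(cfg.n_sessions - 1, 1)
        cov = {"session_trend": trend, "condition": float(session % 2)}
        rng = np.random.default_rng(seeds[i])
        trial, path = _rollout(i, cfg, shooter, goalie, control, cov, rng)
        trial.session_id = session
        trials.append(trial)
        paths.append(path)
    return LabeledDataset(trials, paths, cfg)


# --------------------------------------------------------------------------
# recovery harness
# --------------------------------------------------------------------------
def parameter_recovery_report(fitted, truth: LabeledDataset,
                              holdout_elbos: dict | None = None) -> dict:
    """Compare a fitted model against the generating ground truth.

    Reports per-dimension relative tap error, the relative error of the
    proportional tap (L0), and the mean per-trial correlation between
    posterior-mean and true goal paths.
    """
    from .inference import posterior_mean_path, prep_trial

    true_taps = truth.truth.true_taps
    est_taps = fitted.gen.taps.data
    if est_taps.shape != true_taps.shape:
        raise ValueError("tap shape mismatch between fit and truth")
    tap_rel = np.linalg.norm(est_taps - true_taps, axis=1) / \
        np.linalg.norm(true_taps, axis=1)
    l0_rel = np.abs(est_taps[:, 0] - true_taps[:, 0]) / np.abs(true_taps[:, 0])

    vmax = truth.truth.game.vmax_arr
    corrs, dim_corrs = [], {0: [], 1: [], 2: []}
    for trial, path in zip(truth.trials, truth.goals):
        prepped = prep_trial(trial, vmax, lag=fitted.rec.lag,
                             lead=fitted.rec.lead)
        m = posterior_mean_path(prepped, fitted.rec)
        g = path.g
        # one correlation per trial over the whole goal path
        if np.std(g) > 1e-9 and np.std(m) > 1e-9:
            corrs.append(float(np.corrcoef(m.ravel(), g.ravel())[0, 1]))
        for j in range(3):
            if np.std(g[:, j]) > 1e-6 and np.std(m[:, j]) > 1e-6:
                dim_corrs[j].append(np.corrcoef(m[:, j], g[:, j])[0, 1])
    report = {
        "tap_rel_error": tap_rel,
        "l0_rel_error": l0_rel,
        "mean_goal_correlation": float(np.mean(corrs)) if corrs else np.nan,
        "per_dim_goal_correlation": np.array(
            [np.mean(dim_corrs[j]) if dim_corrs[j] else np.nan
             for j in range(3)]),
        "n_trials": len(truth.trials),
        "eps_hat": np.exp(fitted.gen.log_eps.data),
        "eps_true": np.asarray(truth.truth.true_eps),
    }
    if holdout_elbos:
        report["holdout_elbo"] = dict(holdout_elbos)
    return report
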