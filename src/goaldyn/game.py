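"""Discrete-time penalty-shot environment.

Two players: a "shooter" steers a puck (2-D) toward a goal line on the
right edge of the screen while a "goalie" moves a vertical bar (1-D) to
intercept it.  Screen coordinates are normalized to [-1, 1] in x and y.
The state vector is ``y = (x_puck, y_puck, y_goalie)``; the goalie's
horizontal position is fixed and never stored.  Positions advance by

    y[t+1] = clamp(y[t] + vmax * upsilon[t])

with joystick input ``upsilon`` in [-1, 1] per dimension.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger("goaldyn")

# trial outcomes
SHOOTER_WIN = "shooter_win"
GOALIE_WIN = "goalie_win"
TIMEOUT = "timeout"
TRUNCATED = "truncated"
ONGOING = "ongoing"

OUTCOMES = (SHOOTER_WIN, GOALIE_WIN, TIMEOUT, TRUNCATED)


@dataclass(frozen=True)
class GameConfig:
    """Geometry and kinematics of the penalty-shot screen.

    ``vmax`` holds the per-dimension maximum speeds in screen units per
    time step; in the experiment these were titrated per session, so when
    ingesting recorded data they are estimated as the per-dimension max
    |dy| over the session.  The puck radius and bar half-height are not
    reported dimensions of the original display and default to visually
    plausible values.
    """

    vmax: tuple = (0.02, 0.02, 0.012)
    dt: float = 1.0 / 60.0
    goal_line_x: float = 0.9
    goalie_x: float = 0.75
    bar_half_height: float = 0.12
    puck_radius: float = 0.05
    timeout_s: float = 10.0
    start_x: float = -0.8
    rolling_timeout: bool = True  # timeout clock resets on shooter movement

    def __post_init__(self):
        v = np.asarray(self.vmax, dtype=np.float64)
        if v.shape != (3,) or not np.all(v > 0):
            raise ValueError("vmax must be a positive 3-vector")
        if not (-1.0 < self.goalie_x < self.goal_line_x <= 1.0):
            raise ValueError("require -1 < goalie_x < goal_line_x <= 1")
        if self.bar_half_height <= 0 or self.dt <= 0:
            raise ValueError("bar_half_height and dt must be positive")

    @property
    def vmax_arr(self) -> np.ndarray:
        return np.asarray(self.vmax, dtype=np.float64)

    @property
    def max_timeout_steps(self) -> int:
        return int(np.ceil(self.timeout_s / self.dt))

    def replace(self, **kw) -> "GameConfig":
        return replace(self, **kw)


@dataclass
class TrialTrajectory:
    """One trial: positions, joystick inputs, outcome and covariates.

    ``y`` is (T, 3); ``upsilon`` is (T-1, 3) with columns
    (shooter x, shooter y, goalie y); ``covariates`` maps names (e.g.
    'session_trend', 'condition') to scalars constant within the trial.
    """

    trial_id: int
    y: np.ndarray
    upsilon: np.ndarray
    outcome: str
    covariates: dict = field(default_factory=dict)
    session_id: int = 0
    gaze: np.ndarray | None = None  # optional (T, 2), passed through untouched

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.upsilon = np.asarray(self.upsilon, dtype=np.float64)
        if self.y.ndim != 2 or self.y.shape[1] != 3:
            raise ValueError("y must be (T, 3)")
        if self.upsilon.shape != (self.y.shape[0] - 1, 3):
            raise ValueError("upsilon must be (T-1, 3)")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def n_steps(self) -> int:
        return self.y.shape[0]


def step_dynamics(y, upsilon, config: GameConfig) -> np.ndarray:
    """Advance the screen state one step: clamp(y + vmax * upsilon)."""
    y = np.asarray(y, dtype=np.float64)
    upsilon = np.asarray(upsilon, dtype=np.float64)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(upsilon))):
        raise ValueError(f"non-finite state or input: y={y}, upsilon={upsilon}")
    return np.clip(y + config.vmax_arr * upsilon, -1.0, 1.0)


def check_termination(y, shooter_idle_time: float, config: GameConfig) -> str:
    """Classify a state as terminal or ongoing.

    Goalie interception takes precedence over goal crossing when both hold
    in the same step.  A trial times out when the shooter has produced no
    input for ``timeout_s`` seconds.
    """
    x_puck, y_puck, y_goalie = np.asarray(y, dtype=np.float64)
    r = config.puck_radius
    hit_bar = (abs(x_puck - config.goalie_x) <= r
               and abs(y_puck - y_goalie) <= config.bar_half_height + r)
    if hit_bar:
        return GOALIE_WIN
    if x_puck + r >= config.goal_line_x:
        return SHOOTER_WIN
    if shooter_idle_time >= config.timeout_s:
        return TIMEOUT
    return ONGOING


def initial_state(config: GameConfig) -> np.ndarray:
    """Puck at left-center, goalie bar at vertical center."""
    return np.array([config.start_x, 0.0, 0.0])


def run_trial(shooter_policy, goalie_policy, config: GameConfig,
              seed: int = 0, max_steps: int = 1200,
              trial_id: int = 0, covariates: dict | None = None) -> TrialTrajectory:
    """Roll out one trial under arbitrary policies.

    Policies are callables ``(t, y_history, rng) -> input`` returning the
    shooter's 2-vector / goalie's scalar (or 1-vector) joystick input in
    [-1, 1]; outputs outside that range are clipped with a warning.
    Identical seeds give identical trajectories.
    """
    rng = np.random.default_rng(seed)
    y = [initial_state(config)]
    ups = []
    idle = 0.0
    outcome = TRUNCATED
    clip_warned = False
    for t in range(max_steps):
        u_s = np.atleast_1d(np.asarray(shooter_policy(t, y, rng), dtype=np.float64))
        u_g = np.atleast_1d(np.asarray(goalie_policy(t, y, rng), dtype=np.float64))
        upsilon = np.concatenate([u_s.ravel(), u_g.ravel()])
        if upsilon.shape != (3,):
            raise ValueError("policies must produce 2 + 1 input dimensions")
        if np.any(np.abs(upsilon) > 1.0):
            if not clip_warned:
                warnings.warn("policy output outside [-1, 1]; clipping")
                clip_warned = True
            upsilon = np.clip(upsilon, -1.0, 1.0)
        if np.all(upsilon[:2] == 0.0):
            idle += config.dt
        elif config.rolling_timeout:
            idle = 0.0
        ups.append(upsilon)
        y.append(step_dynamics(y[-1], upsilon, config))
        res = check_termination(y[-1], idle, config)
        if res != ONGOING:
            outcome = res
            break
    return TrialTrajectory(trial_id=trial_id, y=np.array(y),
                           upsilon=np.array(ups), outcome=outcome,
                           covariates=dict(covariates or {}))


def outcome_of_trajectory(y: np.ndarray, config: GameConfig,
                          upsilon: np.ndarray | None = None) -> str:
    """Re-derive the outcome implied by a stored trajectory."""
    idle = 0.0
    for t in range(1, y.shape[0]):
        if upsilon is not None:
            if np.all(upsilon[t - 1, :2] == 0.0):
                idle += config.dt
            elif config.rolling_timeout:
                idle = 0.0
        res = check_termination(y[t], idle, config)
        if res != ONGOING:
            return res
    return TRUNCATED
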