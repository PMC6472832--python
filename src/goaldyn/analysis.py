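"""Behavioral analyses: change-point complexity, predictive-R2 curves for
the final puck position, and sessionwise summaries.

A change point of one joystick dimension is a step where the (smoothed)
input changes sign, is nonzero on both sides, and jumps by at least a
minimal threshold; the per-trial count is a rough proxy for strategic
complexity.  Predictive R2 regresses each trial's final puck vertical
position on a chosen predictor at a fixed offset from trial start or end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .game import SHOOTER_WIN, TrialTrajectory
from .preprocess import gaussian_smooth, velocities

log = logging.getLogger("goaldyn")

CP_THRESHOLD = 1e-6
CP_EDGE_TRIM = 5
MOVEMENT_NORM = 1e-3   # velocity norm defining movement onset


@dataclass
class ChangePointRecord:
    """Per-trial change-point counts (shooter = x + y, goalie = y)."""

    trial_id: int
    shooter: int
    goalie: int
    trial_length: int
    session_id: int = 0
    outcome: str = ""

    def __post_init__(self):
        if min(self.shooter, self.goalie) < 0:
            raise ValueError("counts must be non-negative")
        if max(self.shooter, self.goalie) > 2 * (self.trial_length - 1):
            raise ValueError("counts exceed trial length")


@dataclass
class R2Curve:
    """Coefficient-of-determination curve for one predictor."""

    predictor: str
    alignment: str                     # 'trial_start' | 'trial_end'
    offsets: np.ndarray
    r2: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self):
        if np.any((self.r2 < -1e-9) | (self.r2 > 1 + 1e-9)):
            raise ValueError("R2 out of [0, 1]")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")


def count_change_points(upsilon: np.ndarray, threshold: float = CP_THRESHOLD,
                        edge_trim: int = CP_EDGE_TRIM) -> int:
    """Count sign changes of one joystick dimension.

    The input should already be smoothed; ``edge_trim`` samples are
    dropped at each end to minimize edge effects.
    """
    u = np.asarray(upsilon, dtype=np.float64).ravel()
    if u.size <= 2 * edge_trim + 1:
        warnings.warn("series too short after edge trimming; count = 0")
        return 0
    if edge_trim:
        u = u[edge_trim:-edge_trim]
    a, b = u[:-1], u[1:]
    hits = (np.sign(a) != np.sign(b)) & (a != 0) & (b != 0) & \
        (np.abs(a - b) >= threshold)
    return int(np.count_nonzero(hits))


def trial_change_points(trial: TrialTrajectory, threshold: float = CP_THRESHOLD,
                        edge_trim: int = CP_EDGE_TRIM,
                        smooth: bool = True) -> ChangePointRecord:
    """Change-point record for one trial (inputs smoothed first)."""
    ups = trial.upsilon
    if smooth and ups.shape[0] > 21:
        ups = gaussian_smooth(ups)
    shooter = (count_change_points(ups[:, 0], threshold, edge_trim)
               + count_change_points(ups[:, 1], threshold, edge_trim))
    goalie = count_change_points(ups[:, 2], threshold, edge_trim)
    return ChangePointRecord(trial.trial_id, shooter, goalie,
                             trial.y.shape[0], trial.session_id, trial.outcome)


def movement_onset(y: np.ndarray, norm: float = MOVEMENT_NORM) -> int:
    """First step where the velocity norm exceeds the movement threshold."""
    v = velocities(np.asarray(y, dtype=np.float64))
    n = np.linalg.norm(v, axis=1)
    hits = np.nonzero(n > norm)[0]
    return int(hits[0]) if hits.size else y.shape[0] - 1


# --------------------------------------------------------------------------
# predictive R2
# --------------------------------------------------------------------------
PREDICTORS = ("goal", "velocity", "gaze", "state", "state+goal")


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R2 of an intercept-included least-squares fit."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst <= 0:
        return 0.0
    return float(max(0.0, 1.0 - np.sum(resid ** 2) / sst))


def _predictor_series(trial: TrialTrajectory, goal_path, name: str) -> np.ndarray:
    """Per-step predictor columns aligned with observed steps 0..T-2."""
    y_s = gaussian_smooth(trial.y) if trial.y.shape[0] > 21 else trial.y
    T = trial.y.shape[0]
    vel = velocities(y_s)[:T - 1]
    if name == "velocity":
        return vel[:, :2]
    if name == "state":
        return np.column_stack([y_s[:T - 1], vel])
    if name == "gaze":
        if trial.gaze is None:
            raise ValueError("trial has no gaze columns")
        return trial.gaze[:T - 1]
    if name in ("goal", "state+goal"):
        if goal_path is None:
            raise ValueError(f"predictor {name!r} needs goal paths")
        g = np.asarray(goal_path.g if hasattr(goal_path, "g") else goal_path)
        goals = g[1:T]                     # goal row r pairs position y[r-1]
        if name == "goal":
            return goals[:, :2]            # shooter goal (x, y)
        return np.column_stack([y_s[:T - 1], vel, goals])
    raise ValueError(f"unknown predictor {name!r}")


def final_puck_position(trial: TrialTrajectory) -> float:
    """Vertical puck position at the termination step (smoothed)."""
    y_s = gaussian_smooth(trial.y) if trial.y.shape[0] > 21 else trial.y
    return float(y_s[-1, 1])


def predictive_r2(trials, predictor: str, alignment: str = "trial_start",
                  offsets=None, goal_paths=None,
                  min_trials: int = 10) -> R2Curve:
    """OLS R2 of final puck vertical position on a predictor at each offset.

    ``goal_paths`` supplies per-trial goal series (ground truth or
    posterior means) for the goal-based predictors; multi-column
    predictors are fit jointly.  Offsets with fewer than ``min_trials``
    eligible trials are omitted.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    if alignment not in ("trial_start", "trial_end"):
        raise ValueError("alignment must be trial_start or trial_end")
    if offsets is None:
        offsets = np.arange(0, 60, 2)
    offsets = np.asarray(offsets, dtype=int)

    series, finals = [], []
    for i, t in enumerate(trials):
        gp = goal_paths[i] if goal_paths is not None else None
        series.append(_predictor_series(t, gp, predictor))
        finals.append(final_puck_position(t))
    finals = np.asarray(finals)

    out_off, out_r2, out_n = [], [], []
    for off in offsets:
        X_rows, y_rows = [], []
        for s, f in zip(series, finals):
            idx = off if alignment == "trial_start" else s.shape[0] - 1 - off
            if 0 <= idx < s.shape[0]:
                X_rows.append(s[idx])
                y_rows.append(f)
        if len(y_rows) < min_trials:
            continue
        out_off.append(off)
        out_r2.append(_ols_r2(np.asarray(X_rows), np.asarray(y_rows)))
        out_n.append(len(y_rows))
    return R2Curve(predictor, alignment, np.asarray(out_off),
                   np.asarray(out_r2), np.asarray(out_n))


# --------------------------------------------------------------------------
# sessionwise summaries
# --------------------------------------------------------------------------
def session_summaries(trials, records=None) -> dict:
    """Per-session complexity and win-rate table plus trend regressions.

    Formal tests (one-way ANOVA across sessions, Wald tests on the trend
    and win-rate regressions, Fisher exact tests on consecutive-outcome
    tables with Bonferroni correction) are delegated to scipy/statsmodels
    routines and surfaced in the returned report.
    """
    records = records or [trial_change_points(t) for t in trials]
    df = pd.DataFrame({
        "trial_id": [r.trial_id for r in records],
        "session": [r.session_id for r in records],
        "shooter_cp": [r.shooter for r in records],
        "goalie_cp": [r.goalie for r in records],
        "total_cp": [r.shooter + r.goalie for r in records],
        "win": [t.outcome == SHOOTER_WIN for t in trials],
    })
    per_session = df.groupby("session").agg(
        mean_shooter_cp=("shooter_cp", "mean"),
        mean_goalie_cp=("goalie_cp", "mean"),
        mean_total_cp=("total_cp", "mean"),
        win_rate=("win", "mean"),
        n_trials=("trial_id", "count")).reset_index()

    report = {"per_trial": df, "per_session": per_session}
    if len(per_session) < 2:
        report["trend"] = None
        report["win_vs_complexity"] = None
        return report

    def _regress(x, y):
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if np.ptp(x) == 0:  # a constant regressor carries no slope information
            return {"slope": 0.0, "p": 1.0, "stderr": 0.0}
        r = stats.linregress(x, y)
        return {"slope": r.slope, "p": r.pvalue, "stderr": r.stderr}

    report["trend"] = _regress(per_session["session"],
                               per_session["mean_shooter_cp"])
    report["win_vs_complexity"] = {
        who: _regress(per_session[f"mean_{who}_cp"], per_session["win_rate"])
        for who in ("shooter", "goalie")}

    groups = [g["shooter_cp"].to_numpy() for _, g in df.groupby("session")]
    if all(len(g) > 1 for g in groups):
        f, p = stats.f_oneway(*groups)
        report["anova_sessions"] = {"F": float(f), "p": float(p)}

    # consecutive-outcome independence, Fisher exact + Bonferroni
    fisher_p = []
    for _, g in df.groupby("session"):
        w = g["win"].to_numpy()
        if len(w) < 3 or w.all() or not w.any():
            continue
        table = np.array([[np.sum(w[:-1] & w[1:]), np.sum(w[:-1] & ~w[1:])],
                          [np.sum(~w[:-1] & w[1:]), np.sum(~w[:-1] & ~w[1:])]])
        fisher_p.append(stats.fisher_exact(table)[1])
    if fisher_p:
        alpha = 0.01 / len(fisher_p)   # Bonferroni, 1% family-wise
        report["fisher_consecutive"] = {
            "n_sessions": len(fisher_p),
            "n_significant": int(np.sum(np.asarray(fisher_p) < alpha)),
            "alpha_corrected": alpha}
    return report
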