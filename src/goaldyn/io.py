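"""Readers/writers for the trajectory and goal CSV dialects and the
fitted-model archive.

Trajectory CSV (one row per timestep): trial_id, t, x_puck, y_puck,
y_goalie [, ups_x, ups_y, ups_g, gaze_x, gaze_y]; a per-trial sidecar CSV
carries outcome, session id and covariates.  Coordinates are in the
normalized screen frame (x rightward, y upward, both in [-1, 1]); indices
are 0-based.  The model archive is a directory with a JSON manifest and a
numpy parameter file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .game import OUTCOMES, TrialTrajectory
from .goals import GoalPath
from .inference import (FittedModel, GameConfig, GenerativeModel,
                        RecognitionModel, TrainConfig)

log = logging.getLogger("goaldyn")

ARCHIVE_VERSION = 1
TRAJ_COLS = ["trial_id", "t", "x_puck", "y_puck", "y_goalie"]
UPS_COLS = ["ups_x", "ups_y", "ups_g"]
GAZE_COLS = ["gaze_x", "gaze_y"]


# --------------------------------------------------------------------------
# trajectory CSV
# --------------------------------------------------------------------------
def write_trajectories(trials, path: str | Path) -> None:
    """Write trials as <path>.csv plus <path>_trials.csv sidecar."""
    path = Path(path)
    rows, side = [], []
    for t in trials:
        T = t.y.shape[0]
        df = pd.DataFrame(t.y, columns=["x_puck", "y_puck", "y_goalie"])
        df.insert(0, "t", np.arange(T))
        df.insert(0, "trial_id", t.trial_id)
        ups = np.vstack([t.upsilon, [np.nan, np.nan, np.nan]])
        df[UPS_COLS] = ups
        if t.gaze is not None:
            df[GAZE_COLS] = t.gaze
        rows.append(df)
        side.append({"trial_id": t.trial_id, "outcome": t.outcome,
                     "session_id": t.session_id, **t.covariates})
    pd.concat(rows, ignore_index=True).to_csv(
        path.with_suffix(".csv"), index=False, float_format="%.12g")
    pd.DataFrame(side).to_csv(
        path.parent / (path.stem + "_trials.csv"), index=False,
        float_format="%.12g")


def read_trajectories(path: str | Path) -> list[TrialTrajectory]:
    """Read the trajectory CSV dialect, validating invariants.

    Missing joystick columns are derived from position differences (using
    the sessionwide per-dimension max |dy| as the speed estimate).
    """
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".csv"))
    for c in TRAJ_COLS:
        if c not in df.columns:
            raise ValueError(f"missing column {c!r} in {path}")
    if df.empty:
        log.warning("empty trajectory file %s", path)
        return []
    side_path = path.parent / (path.stem + "_trials.csv")
    side = pd.read_csv(side_path).set_index("trial_id") if side_path.exists() \
        else pd.DataFrame()

    pos = df[["x_puck", "y_puck", "y_goalie"]].to_numpy()
    bad = np.nonzero(np.abs(pos) > 1.0 + 1e-9)[0]
    if bad.size:
        raise ValueError(f"position outside [-1, 1] at row {bad[0] + 2} of {path}")

    has_ups = all(c in df.columns for c in UPS_COLS)
    has_gaze = all(c in df.columns for c in GAZE_COLS)
    vmax = None
    if not has_ups:
        steps = []
        for _, g in df.groupby("trial_id", sort=False):
            steps.append(np.max(np.abs(np.diff(
                g[["x_puck", "y_puck", "y_goalie"]].to_numpy(), axis=0)), axis=0))
        vmax = np.maximum(np.max(steps, axis=0), 1e-12)

    trials = []
    for tid, g in df.groupby("trial_id", sort=False):
        t_idx = g["t"].to_numpy()
        if not np.array_equal(t_idx, np.arange(len(t_idx))):
            raise ValueError(f"non-contiguous t for trial {tid} in {path}")
        y = g[["x_puck", "y_puck", "y_goalie"]].to_numpy()
        if has_ups:
            ups = g[UPS_COLS].to_numpy()[:-1]
        else:
            from .preprocess import derive_control
            ups, _ = derive_control(y, vmax)
        meta = side.loc[tid].to_dict() if len(side) and tid in side.index else {}
        outcome = meta.pop("outcome", "truncated")
        session = int(meta.pop("session_id", 0))
        if outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r} for trial {tid}")
        gaze = g[GAZE_COLS].to_numpy() if has_gaze else None
        trials.append(TrialTrajectory(int(tid), y, ups, outcome,
                                      {k: float(v) for k, v in meta.items()},
                                      session, gaze))
    log.info("read %d trials, %d steps from %s", len(trials),
             sum(t.y.shape[0] for t in trials), path)
    return trials


# --------------------------------------------------------------------------
# goals CSV
# --------------------------------------------------------------------------
def write_goals(goal_paths, trial_ids, path: str | Path) -> None:
    """Goal CSV: trial_id, t (goal row), gx_shooter, gy_shooter, gy_goalie, k."""
    rows = []
    for tid, gp in zip(trial_ids, goal_paths):
        g = gp.g if isinstance(gp, GoalPath) else np.asarray(gp)
        df = pd.DataFrame(g, columns=["gx_shooter", "gy_shooter", "gy_goalie"])
        df.insert(0, "t", np.arange(g.shape[0]))
        df.insert(0, "trial_id", tid)
        ids = getattr(gp, "component_ids", None)
        df["k"] = ids if ids is not None else -1
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(Path(path), index=False,
                                              float_format="%.12g")


def read_goals(path: str | Path) -> dict[int, GoalPath]:
    df = pd.read_csv(path)
    out = {}
    for tid, g in df.groupby("trial_id", sort=False):
        ids = g["k"].to_numpy() if "k" in g.columns else None
        out[int(tid)] = GoalPath(
            g[["gx_shooter", "gy_shooter", "gy_goalie"]].to_numpy(),
            component_ids=ids)
    return out


# --------------------------------------------------------------------------
# model archive
# --------------------------------------------------------------------------
def _flatten(prefix: str, d: dict, arrays: dict, manifest: dict) -> None:
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else k
        if isinstance(v, dict):
            manifest[k] = {}
            _flatten(key, v, arrays, manifest[k])
        elif isinstance(v, np.ndarray):
            arrays[key] = v
            manifest[k] = {"__array__": key}
        else:
            manifest[k] = v


def _unflatten(manifest: dict, arrays) -> dict:
    out = {}
    for k, v in manifest.items():
        if isinstance(v, dict):
            if "__array__" in v:
                out[k] = np.asarray(arrays[v["__array__"]])
            else:
                out[k] = _unflatten(v, arrays)
        else:
            out[k] = v
    return out


def write_model_archive(model: FittedModel, path: str | Path) -> None:
    """Directory archive: manifest.json (shapes, hyperparameters) +
    params.npz (all parameter arrays); read/write round-trips bitwise."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays, manifest = {}, {}
    state = {"gen": model.gen.state_dict(), "rec": model.rec.state_dict()}
    _flatten("", state, arrays, manifest)
    top = {"format_version": ARCHIVE_VERSION, "state": manifest,
           "cfg": (model.cfg.__dict__ | {"hidden": list(model.cfg.hidden),
                                         "rec_hidden": list(model.cfg.rec_hidden)})
           if model.cfg else None,
           "game": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in model.game.__dict__.items()} if model.game else None,
           "vmax": list(model.vmax) if model.vmax is not None else None,
           "n_history": len(model.history)}
    np.savez(path / "params.npz", **arrays)
    (path / "manifest.json").write_text(json.dumps(top, indent=1))
    if model.history:
        hist = pd.DataFrame([{k: v for k, v in h.items() if np.isscalar(v)}
                             for h in model.history])
        hist.to_csv(path / "history.csv", index=False)


def read_model_archive(path: str | Path) -> FittedModel:
    path = Path(path)
    man_file = path / "manifest.json"
    npz_file = path / "params.npz"
    if not man_file.exists() or not npz_file.exists():
        raise FileNotFoundError(f"incomplete model archive at {path}")
    top = json.loads(man_file.read_text())
    if top.get("format_version") != ARCHIVE_VERSION:
        raise ValueError(
            f"archive version {top.get('format_version')} needs migration "
            f"(expected {ARCHIVE_VERSION})")
    with np.load(npz_file) as arrays:
        state = _unflatten(top["state"], arrays)
    gen = GenerativeModel.from_state(state["gen"])
    rec = RecognitionModel.from_state(state["rec"])
    cfg = None
    if top.get("cfg"):
        c = dict(top["cfg"])
        c["hidden"] = tuple(c.get("hidden", ()))
        c["rec_hidden"] = tuple(c.get("rec_hidden", ()))
        cfg = TrainConfig(**c)
    game = None
    if top.get("game"):
        gdict = dict(top["game"])
        gdict["vmax"] = tuple(gdict["vmax"])
        game = GameConfig(**gdict)
    vmax = np.asarray(top["vmax"]) if top.get("vmax") is not None else None
    history = []
    hist_file = path / "history.csv"
    if hist_file.exists():
        history = pd.read_csv(hist_file).to_dict("records")
    return FittedModel(gen, rec, history, cfg, game, vmax)
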