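"""Trajectory preprocessing: normalization, reflect padding, Gaussian
smoothing, joystick-input derivation and state-vector assembly.

The smoothing is designed so the first sample is left invariant: before
convolution the series is prepended with its time-and-sign reflection
about the first sample, ``y[-t] = 2 y[0] - y[t]``, and appended with the
linear extrapolation of its final slope.  Velocities are first differences
of the smoothed positions in screen units per step (dt conversions happen
only at reporting time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("goaldyn")

SMOOTH_WINDOW = 41
SMOOTH_SIGMA = 4.0


@dataclass
class StateSeries:
    """Per-trial state matrix s_t: positions, velocities, covariates, lags."""

    s: np.ndarray                      # (T, d)
    columns: list = field(default_factory=list)

    def __post_init__(self):
        if self.s.ndim != 2:
            raise ValueError("state matrix must be 2-D")
        if self.columns and len(self.columns) != self.s.shape[1]:
            raise ValueError("column names do not match state width")

    @property
    def d(self) -> int:
        return self.s.shape[1]


def normalize_trajectory(raw: np.ndarray, per_coordinate_ranges) -> tuple[np.ndarray, callable]:
    """Affine-map each coordinate onto [-1, 1].

    ``per_coordinate_ranges`` is a sequence of (lo, hi) per column.  Returns
    the normalized array and the inverse (de-normalization) function.
    """
    raw = np.asarray(raw, dtype=np.float64)
    ranges = np.asarray(per_coordinate_ranges, dtype=np.float64)
    lo, hi = ranges[:, 0], ranges[:, 1]
    width = hi - lo
    if np.any(width <= 0):
        raise ValueError("coordinate ranges must have positive width")
    out = 2.0 * (raw - lo) / width - 1.0

    def denormalize(z):
        return (np.asarray(z) + 1.0) / 2.0 * width + lo

    return out, denormalize


def reflect_pad(y: np.ndarray, pad_len: int) -> np.ndarray:
    """Prepend the time-and-sign reflection; append the linear extrapolation.

    Prefix obeys ``y[-t] = 2 y[0] - y[t]``; the suffix continues the slope
    of the last two samples.
    """
    y = np.asarray(y, dtype=np.float64)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    T = y.shape[0]
    if T <= pad_len:
        raise ValueError(f"series length {T} must exceed pad_len {pad_len}")
    prefix = 2.0 * y[0] - y[1:pad_len + 1][::-1]
    slope = y[-1] - y[-2] if T >= 2 else np.zeros(y.shape[1])
    steps = np.arange(1, pad_len + 1)[:, None]
    suffix = y[-1] + steps * slope
    out = np.concatenate([prefix, y, suffix], axis=0)
    return out[:, 0] if squeeze else out


def gaussian_kernel(w: int = SMOOTH_WINDOW, sigma: float = SMOOTH_SIGMA) -> np.ndarray:
    """Truncated discrete Gaussian, renormalized to unit sum."""
    if w % 2 == 0:
        raise ValueError("kernel length must be odd (centered)")
    t = np.arange(w) - w // 2
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(y: np.ndarray, w: int = SMOOTH_WINDOW,
                    sigma: float = SMOOTH_SIGMA) -> np.ndarray:
    """Smooth with a centered Gaussian after reflect padding; crop to T.

    The padding construction keeps the first sample invariant.
    """
    y = np.asarray(y, dtype=np.float64)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    kernel = gaussian_kernel(w, sigma)
    pad = w // 2
    padded = reflect_pad(y, pad)
    out = np.empty_like(y)
    for j in range(y.shape[1]):
        out[:, j] = np.convolve(padded[:, j], kernel, mode="valid")
    return out[:, 0] if squeeze else out


def derive_control(y_smoothed: np.ndarray, vmax) -> tuple[np.ndarray, int]:
    """Invert the screen dynamics: upsilon = clip(diff(y) / vmax, [-1, 1]).

    Returns the (T-1, 3) joystick series and the number of clipped entries
    (smoothing can overshoot the speed limit slightly).
    """
    vmax = np.asarray(vmax, dtype=np.float64)
    if np.any(vmax <= 0):
        raise ValueError("vmax must be positive")
    raw = np.diff(np.asarray(y_smoothed, dtype=np.float64), axis=0) / vmax
    n_clipped = int(np.sum(np.abs(raw) > 1.0))
    if n_clipped:
        log.debug("derive_control clipped %d entries", n_clipped)
    return np.clip(raw, -1.0, 1.0), n_clipped


def velocities(y_smoothed: np.ndarray) -> np.ndarray:
    """First differences in units per step; v[0] uses the padded estimate.

    With the sign-reflection padding, y[-1] = 2 y[0] - y[1], so the backward
    difference at t=0 equals the forward difference y[1] - y[0].
    """
    y = np.asarray(y_smoothed, dtype=np.float64)
    v = np.empty_like(y)
    v[1:] = np.diff(y, axis=0)
    v[0] = y[1] - y[0]
    return v


def build_state(y_smoothed: np.ndarray, covariates: dict | None = None,
                lags: int = 0) -> StateSeries:
    """Assemble s_t = (positions, velocities, covariates, lagged positions).

    Width d = 6 + n_covariates + 3 * lags.  Lagged positions are clamped at
    the trial start (lag rows before t=0 repeat y[0]).
    """
    y = np.asarray(y_smoothed, dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite positions in state input")
    T = y.shape[0]
    cols = [y, velocities(y)]
    names = ["x_puck", "y_puck", "y_goalie", "vx_puck", "vy_puck", "vy_goalie"]
    covariates = covariates or {}
    for name, val in covariates.items():
        val = float(val)
        if not np.isfinite(val):
            raise ValueError(f"non-finite covariate {name}")
        cols.append(np.full((T, 1), val))
        names.append(name)
    for l in range(1, lags + 1):
        lagged = np.concatenate([np.repeat(y[:1], min(l, T), axis=0), y[:-l]], axis=0)[:T]
        cols.append(lagged)
        names.extend(f"{n}_lag{l}" for n in ("x_puck", "y_puck", "y_goalie"))
    return StateSeries(np.concatenate(cols, axis=1), names)
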