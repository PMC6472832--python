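"""PID control model linking latent goals to joystick movement.

Each player's control error is e_t = g_t - y_t (goal minus position).
Increments of the latent control signal u follow a three-tap convolution
of the error history,

    du_t = L0 e_t + L1 e_{t-1} + L2 e_{t-2},

where the taps derive from proportional / integral / derivative constants:

    L = kappa * (1 + dt/Ti + Td/dt,  -1 - 2 Td/dt,  Td/dt).

Pure proportional control (kappa=1, integral and derivative action off)
gives taps (1, -1, 0) and telescopes to u_t = e_t.  Observed joystick
input is the saturating link upsilon = tanh(u); control noise is Gaussian
with per-dimension scale eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ControlParams", "pid_taps", "predicted_control",
           "control_loglik", "invert_joystick", "PROPORTIONAL_TAPS"]

PROPORTIONAL_TAPS = np.array([1.0, -1.0, 0.0])
GAUSS_CONST = 0.5 * np.log(2.0 * np.pi)


def pid_taps(kappa: float, Ti: float, Td: float, dt: float) -> np.ndarray:
    """Convert (kappa, Ti, Td) to the 3-tap filter (L0, L1, L2).

    ``Ti`` may be ``inf`` to switch integral action off; ``Td`` must be
    non-negative.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if Td < 0:
        raise ValueError("Td must be non-negative")
    inv_Ti = 0.0 if np.isinf(Ti) else 1.0 / Ti
    r = Td / dt
    return kappa * np.array([1.0 + dt * inv_Ti + r, -1.0 - 2.0 * r, r])


@dataclass
class ControlParams:
    """Per-dimension 3-tap filters and control-noise scales.

    ``taps`` is (3, 3): rows are the output dimensions (shooter x,
    shooter y, goalie y), columns the filter taps (L0, L1, L2).
    ``eps`` is the positive noise std per dimension.
    """

    taps: np.ndarray = field(default_factory=lambda: np.tile(PROPORTIONAL_TAPS, (3, 1)))
    eps: np.ndarray = field(default_factory=lambda: np.full(3, 0.1))

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=np.float64)
        self.eps = np.asarray(self.eps, dtype=np.float64)
        if self.taps.shape != (3, 3):
            raise ValueError("taps must be (3, 3): dimension x tap")
        if self.eps.shape != (3,) or np.any(self.eps <= 0):
            raise ValueError("eps must be positive per dimension")

    @classmethod
    def from_pid(cls, kappas, Tis, Tds, dt: float, eps) -> "ControlParams":
        taps = np.stack([pid_taps(k, ti, td, dt)
                         for k, ti, td in zip(kappas, Tis, Tds)])
        return cls(taps=taps, eps=np.asarray(eps, dtype=np.float64))

    @classmethod
    def proportional(cls, kappas=(1.0, 1.0, 1.0), eps=(0.1, 0.1, 0.1)) -> "ControlParams":
        taps = np.outer(np.asarray(kappas, dtype=np.float64), PROPORTIONAL_TAPS)
        return cls(taps=taps, eps=np.asarray(eps, dtype=np.float64))


def predicted_control(u_prev, e_hist, params: ControlParams) -> np.ndarray:
    """u*_t = u_{t-1} + sum_tau L_tau e_{t-tau}.

    ``e_hist`` holds the last three errors ordered newest-first:
    (e_t, e_{t-1}, e_{t-2}), each a 3-vector (or shape (3, 3) array).
    """
    e_hist = np.asarray(e_hist, dtype=np.float64)
    if e_hist.shape != (3, 3):
        raise ValueError("e_hist must be (3 lags, 3 dims), newest first")
    du = np.einsum("dt,td->d", params.taps, e_hist)
    return np.asarray(u_prev, dtype=np.float64) + du


def control_loglik(u_obs, u_star, eps) -> float:
    """Sum of independent Gaussian log-densities N(u_obs; u_star, eps^2)."""
    u_obs = np.asarray(u_obs, dtype=np.float64)
    u_star = np.asarray(u_star, dtype=np.float64)
    eps = np.broadcast_to(np.asarray(eps, dtype=np.float64), u_obs.shape)
    if np.any(eps <= 0):
        raise ValueError("eps must be positive")
    z = (u_obs - u_star) / eps
    return float(np.sum(-np.log(eps) - GAUSS_CONST - 0.5 * z * z))


def invert_joystick(upsilon, delta: float = 1e-5) -> tuple[np.ndarray, float]:
    """Recover latent control u = atanh(upsilon), clipping near saturation.

    Saturated inputs (|upsilon| >= 1 - delta) are clipped before inversion
    so u stays bounded by atanh(1 - delta); the fraction of saturated
    entries is returned (large fractions make goal inference for those
    steps weakly identified, which the training hinge penalty addresses).
    """
    upsilon = np.asarray(upsilon, dtype=np.float64)
    if np.any(np.abs(upsilon) > 1.0 + 1e-12):
        raise ValueError("|upsilon| must be <= 1")
    sat_frac = float(np.mean(np.abs(upsilon) >= 1.0 - delta)) if upsilon.size else 0.0
    u = np.arctanh(np.clip(upsilon, -(1.0 - delta), 1.0 - delta))
    return u, sat_frac
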