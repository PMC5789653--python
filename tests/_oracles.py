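"""Independent brute-force oracles used to cross-check the implementation.

These recompute quantities from raw formulas (plain numpy, no package
internals) so that solver and oracle can disagree.
"""

from __future__ import annotations

import numpy as np


def grid_scan_equilibrium(
    sensor_sign: int,
    alpha: float,
    beta: float,
    effector_sign: int,
    p0: float,
    gain: float,
    k: float,
    n_grid: int = 20001,
) -> tuple[float, int, float]:
    """Locate the fixed point of P -> g(f(P)) by dense sign-change scanning.

    Returns (bracket midpoint, number of sign changes, grid step).
    """
    p = np.linspace(p0, p0 + gain, n_grid)
    h = np.exp(alpha + sensor_sign * beta * p)
    frac = h / (h + k) if effector_sign > 0 else k / (h + k)
    resid = p0 + gain * frac - p
    pos = resid > 0
    changes = np.flatnonzero(pos[:-1] & ~pos[1:])
    step = (gain) / (n_grid - 1)
    if len(changes) == 0:
        # root exactly at an endpoint
        idx = 0 if abs(resid[0]) < abs(resid[-1]) else n_grid - 2
        return float(0.5 * (p[idx] + p[idx + 1])), int(np.sum(resid == 0.0)), step
    mid = 0.5 * (p[changes[0]] + p[changes[0] + 1])
    return float(mid), len(changes), step


def grid_scan_heating(
    thresholds: tuple[float, ...],
    power: float,
    k: float,
    t_ext: float,
    n_grid: int = 200001,
) -> tuple[float, float, float]:
    """Steady temperature of a radiator house by dense net-flux scanning.

    Net flux ``p * count(T) - k (T - T_ext)`` starts non-negative at cold
    temperatures and ends negative at hot ones; the steady temperature is
    where it last turns negative. Returns (temperature, energy, grid step).
    """
    t_lo = min(t_ext, min(thresholds)) - 1.0
    t_hi = max(t_ext, max(thresholds)) + 1.0
    t = np.linspace(t_lo, t_hi, n_grid)
    count = (t[:, None] < np.asarray(thresholds)[None, :]).sum(axis=1)
    net = power * count - k * (t - t_ext)
    neg = np.flatnonzero(net < 0)
    step = (t_hi - t_lo) / (n_grid - 1)
    if len(neg) == 0:  # never negative: warmest admissible point is t_hi
        return float(t[-1]), float(k * (t[-1] - t_ext)), step
    idx = neg[0]
    t_star = float(0.5 * (t[idx - 1] + t[idx])) if idx > 0 else float(t[0])
    return t_star, float(k * (t_star - t_ext)), step


def pearson_closed_form(x, y) -> float:
    """Direct evaluation of sum((x-xbar)(y-ybar)) / sqrt(...)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))
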