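"""Negative-feedback loops between a regulated parameter and its controlling hormone.

A loop has two arms. The *sensor* arm is the hormone's response to the
parameter (PTH suppressed by calcium; insulin stimulated by glucose; TSH
suppressed by FT4). The *effector* arm is the parameter's response to the
hormone (calcium raised by PTH; glucose lowered by insulin). At steady state
the two arms are solved simultaneously: the ambient (parameter, hormone)
level of an individual is the intersection point of the two curves.

Functional forms
----------------
The sensor is log-linear, ``H = exp(alpha ± beta * P)`` — hormone
concentrations stay strictly positive and the log-linear shape follows the
convention used for the TSH–FT4 relationship. The effector is a saturating
hyperbola, ``P = P0 + G * H / (H + K)`` (stimulatory) or
``P = P0 + G * K / (H + K)`` (suppressive) — a bounded physiological output
between a basal level ``P0`` and a ceiling ``P0 + G``. Both arms are strictly
monotone, so a negative loop (one arm stimulatory, the other suppressive) has
a strictly decreasing composition ``P -> g(f(P))`` and therefore a unique
fixed point on ``[P0, P0 + G]``.

Units are abstract parameter/hormone units; no conversion layer is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, InputError, ModelError

__all__ = [
    "STIMULATORY",
    "SUPPRESSIVE",
    "SensorCurve",
    "EffectorCurve",
    "FeedbackSystem",
    "EquilibriumPoint",
    "evaluate_curve",
    "solve_equilibrium",
    "predefined_system",
    "PREDEFINED_DIRECTIONS",
]

STIMULATORY = "stimulatory"
SUPPRESSIVE = "suppressive"
_DIRECTIONS = (STIMULATORY, SUPPRESSIVE)

ArrayLike = Union[float, np.ndarray]


def _direction_sign(direction: str) -> int:
    return +1 if direction == STIMULATORY else -1


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise InputError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise InputError(f"{name} must be finite, got {value!r}")


def _validate_input(x: ArrayLike, lo: float, hi: float) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("curve input must be finite")
    if np.any(arr < lo) or np.any(arr > hi):
        raise DomainError(
            f"input outside curve domain [{lo}, {hi}]: "
            f"range [{arr.min()}, {arr.max()}]"
        )
    return arr


@dataclass(frozen=True)
class SensorCurve:
    """Hormone response to the parameter: ``H = exp(alpha ± beta * P)``.

    Parameters
    ----------
    direction
        ``"stimulatory"`` (hormone rises with the parameter, e.g. insulin
        with glucose) or ``"suppressive"`` (hormone falls, e.g. PTH with
        calcium). The sign of ``beta`` in the exponent follows the direction.
    alpha
        Log-intercept (dimensionless).
    beta
        Log-slope magnitude, per parameter unit; must be > 0 so the curve is
        strictly monotone.
    domain
        Closed interval of admissible parameter values.
    """

    direction: str
    alpha: float
    beta: float
    domain: tuple[float, float] = (0.0, math.inf)

    role = "sensor"

    def __post_init__(self) -> None:
        _check_direction(self.direction)
        _check_finite("alpha", self.alpha)
        _check_finite("beta", self.beta)
        if self.beta <= 0:
            raise InputError(f"beta must be > 0 for strict monotonicity, got {self.beta}")
        lo, hi = self.domain
        if not lo < hi:
            raise InputError(f"domain must satisfy min < max, got {self.domain}")

    @property
    def sign(self) -> int:
        """+1 for stimulatory, -1 for suppressive."""
        return _direction_sign(self.direction)

    def __call__(self, p: ArrayLike) -> ArrayLike:
        arr = _validate_input(p, *self.domain)
        out = np.exp(self.alpha + self.sign * self.beta * arr)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EffectorCurve:
    """Parameter response to the hormone: a saturating hyperbola.

    Stimulatory: ``P = P0 + G * H / (H + K)`` — rises from P0 toward P0 + G.
    Suppressive: ``P = P0 + G * K / (H + K)`` — falls from P0 + G toward P0.

    Parameters
    ----------
    direction
        Whether the hormone raises or lowers the parameter.
    p0
        Basal parameter level (>= 0), the hormone-independent floor.
    gain
        Dynamic range G (> 0); output is bounded by ``p0 + gain``.
    k
        Half-activation hormone level (> 0).
    domain
        Closed interval of admissible hormone values.
    """

    direction: str
    p0: float
    gain: float
    k: float
    domain: tuple[float, float] = (0.0, math.inf)

    role = "effector"

    def __post_init__(self) -> None:
        _check_direction(self.direction)
        for name in ("p0", "gain", "k"):
            _check_finite(name, getattr(self, name))
        if self.p0 < 0:
            raise InputError(f"p0 must be >= 0, got {self.p0}")
        if self.gain <= 0:
            raise InputError(f"gain must be > 0 for strict monotonicity, got {self.gain}")
        if self.k <= 0:
            raise InputError(f"k must be > 0, got {self.k}")
        lo, hi = self.domain
        if not lo < hi:
            raise InputError(f"domain must satisfy min < max, got {self.domain}")

    @property
    def sign(self) -> int:
        return _direction_sign(self.direction)

    def __call__(self, h: ArrayLike) -> ArrayLike:
        arr = _validate_input(h, *self.domain)
        frac = arr / (arr + self.k) if self.sign > 0 else self.k / (arr + self.k)
        out = self.p0 + self.gain * frac
        return float(out) if np.ndim(out) == 0 else out

    def inverse(self, p: ArrayLike) -> ArrayLike:
        """Hormone level producing parameter level ``p`` (closed form).

        Defined on the open interval ``(p0, p0 + gain)``; the bounds map to
        hormone levels 0 and infinity.
        """
        arr = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InputError("inverse input must be finite")
        lo, hi = self.p0, self.p0 + self.gain
        if np.any(arr <= lo) or np.any(arr >= hi):
            raise DomainError(
                f"effector inverse defined only on open interval ({lo}, {hi})"
            )
        if self.sign > 0:
            out = self.k * (arr - lo) / (hi - arr)
        else:
            out = self.k * (hi - arr) / (arr - lo)
        return float(out) if out.ndim == 0 else out


ResponseCurve = Union[SensorCurve, EffectorCurve]


def evaluate_curve(curve: ResponseCurve, x: ArrayLike) -> ArrayLike:
    """Evaluate a response curve at ``x`` (thin functional wrapper)."""
    return curve(x)


# Sensor/effector directions of the three predefined negative-feedback systems.
PREDEFINED_DIRECTIONS: dict[str, tuple[str, str]] = {
    "calcium_pth": (SUPPRESSIVE, STIMULATORY),
    "glucose_insulin": (STIMULATORY, SUPPRESSIVE),
    "ft4_tsh": (SUPPRESSIVE, STIMULATORY),
}


@dataclass(frozen=True)
class FeedbackSystem:
    """A paired sensor + effector forming one negative-feedback loop.

    One instance is one individual's parameterization; a population is many
    instances drawn around a template.
    """

    name: str
    sensor: SensorCurve
    effector: EffectorCurve
    units_p: str = "parameter units"
    units_h: str = "hormone units"

    def __post_init__(self) -> None:
        if self.sensor.sign == self.effector.sign:
            raise InputError(
                "negative feedback requires opposite arm directions; "
                f"both arms of {self.name!r} are {self.sensor.direction}"
            )
        if self.name in PREDEFINED_DIRECTIONS:
            sdir, edir = PREDEFINED_DIRECTIONS[self.name]
            if (self.sensor.direction, self.effector.direction) != (sdir, edir):
                raise InputError(
                    f"system {self.name!r} must have sensor {sdir} / effector {edir}"
                )

    def composition(self, p: ArrayLike) -> ArrayLike:
        """The loop map ``P -> g(f(P))``; strictly decreasing for valid loops."""
        return self.effector(self.sensor(p))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "units_p": self.units_p,
            "units_h": self.units_h,
            "sensor": {
                "direction": self.sensor.direction,
                "alpha": self.sensor.alpha,
                "beta": self.sensor.beta,
            },
            "effector": {
                "direction": self.effector.direction,
                "p0": self.effector.p0,
                "gain": self.effector.gain,
                "k": self.effector.k,
            },
        }

    @classmethod
    def from_dict(cls, block: dict) -> "FeedbackSystem":
        try:
            s, e = block["sensor"], block["effector"]
            return cls(
                name=block["name"],
                sensor=SensorCurve(s["direction"], float(s["alpha"]), float(s["beta"])),
                effector=EffectorCurve(
                    e["direction"], float(e["p0"]), float(e["gain"]), float(e["k"])
                ),
                units_p=block.get("units_p", "parameter units"),
                units_h=block.get("units_h", "hormone units"),
            )
        except KeyError as exc:
            raise InputError(f"missing key in system block: {exc}") from exc


# Template parameters for the predefined systems. The sign analysis depends
# only on arm directions, not magnitudes, so the templates use abstract
# units chosen so the template equilibrium is exactly (P*, H*) = (1, 1):
# alpha = -sign * beta at P = 1 makes f(1) = 1, and P0 + G/2 = 1 at H = K = 1.
_TEMPLATE_UNITS = {
    "calcium_pth": ("calcium (arb. units)", "PTH (arb. units)"),
    "glucose_insulin": ("glucose (arb. units)", "insulin (arb. units)"),
    "ft4_tsh": ("FT4 (arb. units)", "TSH (arb. units)"),
}


def predefined_system(name: str) -> FeedbackSystem:
    """Template loop for ``calcium_pth``, ``glucose_insulin`` or ``ft4_tsh``."""
    if name not in PREDEFINED_DIRECTIONS:
        raise InputError(
            f"unknown system {name!r}; choose from {sorted(PREDEFINED_DIRECTIONS)}"
        )
    sdir, edir = PREDEFINED_DIRECTIONS[name]
    alpha = 1.0 if sdir == SUPPRESSIVE else -1.0
    units_p, units_h = _TEMPLATE_UNITS[name]
    return FeedbackSystem(
        name=name,
        sensor=SensorCurve(direction=sdir, alpha=alpha, beta=1.0),
        effector=EffectorCurve(direction=edir, p0=0.5, gain=1.0, k=1.0),
        units_p=units_p,
        units_h=units_h,
    )


@dataclass(frozen=True)
class EquilibriumPoint:
    """The intersection point of the two arms of one individual's loop."""

    p_star: float
    h_star: float
    residual: float
    iterations: int


def solve_equilibrium(
    system: FeedbackSystem,
    tolerance: float = 1e-9,
    max_iter: int = 200,
) -> EquilibriumPoint:
    """Solve the loop's fixed point ``P* = g(f(P*))`` by bracketed root finding.

    The composition maps ``[P0, P0 + G]`` into itself and is strictly
    decreasing under negative feedback, so ``F(P) = g(f(P)) - P`` changes
    sign exactly once on that bracket. Brent's method locates the root; if
    the residual ``|F(P*)|`` still exceeds ``tolerance`` (steep composition),
    plain bisection refines the surviving bracket until it does not.

    Raises
    ------
    ModelError
        If the bracket endpoints fail to straddle a sign change — impossible
        for a valid system, surfaced rather than clamped.
    """
    if not tolerance > 0:
        raise InputError(f"tolerance must be > 0, got {tolerance}")
    lo = system.effector.p0
    hi = lo + system.effector.gain

    def f_res(p: float) -> float:
        return system.composition(p) - p

    f_lo, f_hi = f_res(lo), f_res(hi)
    if f_lo == 0.0:
        root, iters = lo, 0
    elif f_hi == 0.0:
        root, iters = hi, 0
    elif f_lo < 0.0 or f_hi > 0.0:
        raise ModelError(
            f"no sign change of g(f(P)) - P on [{lo}, {hi}] "
            f"(F(lo)={f_lo:.3g}, F(hi)={f_hi:.3g}); system is not a valid "
            "negative-feedback loop"
        )
    else:
        root, info = brentq(
            f_res, lo, hi, xtol=min(tolerance, 1e-12), rtol=1e-14,
            maxiter=max_iter, full_output=True,
        )
        iters = info.iterations
        if abs(f_res(root)) > tolerance:
            # Steep composition: refine by bisection on the tightest bracket
            # around the Brent root that still straddles the sign change.
            blo, bhi = lo, hi
            width = max(abs(root) * 1e-9, 1e-12)
            if f_res(max(lo, root - width)) > 0:
                blo = max(lo, root - width)
            if f_res(min(hi, root + width)) < 0:
                bhi = min(hi, root + width)
            while iters < max_iter:
                mid = 0.5 * (blo + bhi)
                fm = f_res(mid)
                iters += 1
                if abs(fm) <= tolerance or bhi - blo <= 4 * np.finfo(float).eps * max(1.0, abs(mid)):
                    root = mid
                    break
                if fm > 0:
                    blo = mid
                else:
                    bhi = mid
            else:
                root = 0.5 * (blo + bhi)

    residual = abs(f_res(root))
    return EquilibriumPoint(
        p_star=float(root),
        h_star=float(system.sensor(root)),
        residual=float(residual),
        iterations=int(iters),
    )


def _solve_equilibria_bisect(
    systems: list[FeedbackSystem], n_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bisection of many loops' fixed points at once.

    Used by the cohort simulator for throughput; agrees with
    :func:`solve_equilibrium` to well below its default tolerance
    (bracket width ``G * 2**-n_iter``).
    """
    alpha = np.array([s.sensor.alpha for s in systems])
    beta = np.array([s.sensor.beta for s in systems])
    ssign = np.array([s.sensor.sign for s in systems])
    p0 = np.array([s.effector.p0 for s in systems])
    gain = np.array([s.effector.gain for s in systems])
    k = np.array([s.effector.k for s in systems])
    esign = np.array([s.effector.sign for s in systems])

    def comp(p: np.ndarray) -> np.ndarray:
        h = np.exp(alpha + ssign * beta * p)
        frac = np.where(esign > 0, h / (h + k), k / (h + k))
        return p0 + gain * frac

    lo = p0.copy()
    hi = p0 + gain
    if np.any(comp(lo) - lo < 0) or np.any(comp(hi) - hi > 0):
        raise ModelError("bracket endpoints do not straddle the fixed point")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = comp(mid) - mid > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    p_star = 0.5 * (lo + hi)
    h_star = np.exp(alpha + ssign * beta * p_star)
    return p_star, h_star
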