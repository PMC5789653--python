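"""A heating-system analogy for homeostasis without a set point.

A house is heated by a four-element radiator with no thermostat: one element
switches on when the indoor temperature drops below 22 °C, a second below
20 °C, a third below 18 °C and the fourth below 16 °C. The house's steady
temperature is not programmed anywhere — it is the level at which heat gain
balances heat loss, and it depends on the radiator, the house's heat-loss
coefficient and the outdoor temperature. A thermostat-controlled house, by
contrast, holds a programmed set temperature S by deploying whatever power
that requires (capped at the same total power as the four elements).

The "two towns" experiment draws many houses with varying heat-loss
coefficients. In the thermostat town (set temperatures drawn independently
of heat loss) warmer houses consume more energy: temperature and energy
correlate positively. In the radiator town leakier houses run colder AND
recruit more elements: the correlation is negative. The two towns mirror
the set-point and equilibrium-point predictions for hormone/parameter
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError, UndefinedCorrelationError

__all__ = [
    "Radiator",
    "House",
    "TownSpec",
    "SteadyState",
    "TwoTownsResult",
    "active_elements",
    "steady_state",
    "simulate_dynamics",
    "simulate_town",
    "two_towns",
]

RADIATOR = "radiator"
THERMOSTAT = "thermostat"

FIXED_POINT = "fixed_point"
THRESHOLD_DUTY_CYCLE = "threshold_duty_cycle"
THERMOSTAT_HELD = "thermostat_held"
THERMOSTAT_SATURATED = "thermostat_saturated"


@dataclass(frozen=True)
class Radiator:
    """Element activation thresholds (°C, strictly descending) and per-element power (kW).

    Element i switches on when the temperature drops strictly below its
    threshold; at exactly the threshold it is off ("comes on below"). There
    is no hysteresis: the active count is a pure function of the current
    temperature.
    """

    thresholds: tuple[float, ...] = (22.0, 20.0, 18.0, 16.0)
    power: float = 1.0

    def __post_init__(self) -> None:
        if len(self.thresholds) < 1:
            raise InputError("radiator needs at least one element")
        if any(b >= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise InputError(
                f"thresholds must be strictly descending, got {self.thresholds}"
            )
        if not self.power > 0:
            raise InputError(f"element power must be > 0, got {self.power}")

    @property
    def n_elements(self) -> int:
        return len(self.thresholds)

    @property
    def max_power(self) -> float:
        """All elements on — also the thermostat regime's power cap."""
        return self.power * self.n_elements

    def active_elements(self, t: float) -> int:
        """Number of elements on at temperature ``t`` (0..n, step function)."""
        if not np.isfinite(t):
            raise InputError(f"temperature must be finite, got {t}")
        return int(sum(t < theta for theta in self.thresholds))

    def heat_output(self, t: float) -> float:
        return self.power * self.active_elements(t)


def active_elements(radiator: Radiator, t: float) -> int:
    """Module-level wrapper over :meth:`Radiator.active_elements`."""
    return radiator.active_elements(t)


@dataclass(frozen=True)
class House:
    """One house: heat-loss coefficient k (kW/°C), thermal capacitance C
    (kWh/°C), outdoor temperature (°C), and a heating regime."""

    k: float
    t_ext: float
    c: float = 2.0
    regime: str = RADIATOR
    radiator: Radiator = field(default_factory=Radiator)
    setpoint: float | None = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise InputError(f"heat-loss coefficient k must be > 0, got {self.k}")
        if not self.c > 0:
            raise InputError(f"thermal capacitance must be > 0, got {self.c}")
        if not np.isfinite(self.t_ext):
            raise InputError(f"t_ext must be finite, got {self.t_ext}")
        if self.regime not in (RADIATOR, THERMOSTAT):
            raise ConfigError(f"regime must be {RADIATOR!r} or {THERMOSTAT!r}")
        if self.regime == THERMOSTAT and self.setpoint is None:
            raise ConfigError("thermostat regime requires a setpoint")


@dataclass(frozen=True)
class SteadyState:
    temperature: float  # °C
    energy: float  # kW, heating power at steady state
    mode: str


def steady_state(house: House) -> SteadyState:
    """Steady indoor temperature and heating power, ``losses = gains``.

    Radiator regime: solve ``p * active_elements(T) = k (T - T_ext)``. The
    heat-output step function is non-increasing and the loss line strictly
    increasing, so the crossing is unique. If the loss line crosses inside a
    constant step, that intersection is a true fixed point; if it crosses at
    a step discontinuity the temperature pins to the threshold and the
    heater duty-cycles, delivering exactly the loss ``k (θ - T_ext)``.

    Thermostat regime: hold ``T = S`` at power ``k (S - T_ext)`` unless that
    exceeds the cap (all-elements power), in which case the house saturates
    at ``T = T_ext + cap / k``.
    """
    if house.regime == THERMOSTAT:
        demand = house.k * (house.setpoint - house.t_ext)
        cap = house.radiator.max_power
        if demand <= 0.0:
            # Outdoors at or above the set temperature: heating off, the
            # house passively sits at T_ext (this model has no cooling).
            return SteadyState(temperature=house.t_ext, energy=0.0, mode=FIXED_POINT)
        if demand > cap:
            return SteadyState(
                temperature=house.t_ext + cap / house.k,
                energy=cap,
                mode=THERMOSTAT_SATURATED,
            )
        return SteadyState(temperature=house.setpoint, energy=demand, mode=THERMOSTAT_HELD)

    rad, k, t_ext = house.radiator, house.k, house.t_ext
    th = rad.thresholds
    n = rad.n_elements
    # Enumerate the constant steps: m elements on holds on [lower_m, upper_m).
    for m in range(n + 1):
        upper = np.inf if m == 0 else th[m - 1]
        lower = -np.inf if m == n else th[m]
        t_candidate = t_ext + m * rad.power / k
        if lower <= t_candidate < upper:
            return SteadyState(
                temperature=t_candidate, energy=m * rad.power, mode=FIXED_POINT
            )
    # No step contains its own balance point: the loss line crosses at a
    # threshold discontinuity; the temperature pins there.
    for theta in th:
        loss = k * (theta - t_ext)
        m_above = rad.active_elements(theta)  # elements on just at/above θ
        if m_above * rad.power <= loss <= (m_above + 1) * rad.power:
            return SteadyState(
                temperature=theta, energy=loss, mode=THRESHOLD_DUTY_CYCLE
            )
    raise InputError("no steady state found (unreachable for a valid house)")


def simulate_dynamics(
    house: House,
    t0: float,
    dt: float = 0.01,
    duration: float = 48.0,
    controller_gain: float = 50.0,
    k_override: float | None = None,
) -> pd.DataFrame:
    """Explicit-Euler integration of ``C dT/dt = q(T) - k (T - T_ext)``.

    For a radiator house ``q(T)`` is the step output of the elements;
    duty-cycling at a threshold appears as a small oscillation around it.
    For a thermostat house ``q(T)`` is a continuously modulated power
    ``clip(K_p (S - T), 0, cap)`` — a high-gain proportional controller
    capped at the all-elements power.

    Returns a frame with columns ``time`` (h), ``temperature`` (°C),
    ``power`` (kW). ``k_override`` admits k = 0 (perfect insulation) for
    trajectory exploration only — a steady state need not exist then.
    """
    if not dt > 0:
        raise ConfigError(f"dt must be > 0, got {dt}")
    k = house.k if k_override is None else float(k_override)
    if k < 0:
        raise ConfigError(f"k_override must be >= 0, got {k_override}")
    rate = k + (controller_gain if house.regime == THERMOSTAT else 0.0)
    if rate > 0 and dt >= house.c / rate:
        raise ConfigError(
            f"unstable step: dt={dt} must be < C/k' = {house.c / rate:.4g} h"
        )
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    temps = np.empty(n_steps + 1)
    powers = np.empty(n_steps + 1)
    cap = house.radiator.max_power
    t = float(t0)
    for i in range(n_steps + 1):
        if house.regime == RADIATOR:
            q = house.radiator.heat_output(t)
        else:
            q = float(np.clip(controller_gain * (house.setpoint - t), 0.0, cap))
        temps[i] = t
        powers[i] = q
        t = t + dt * (q - k * (t - house.t_ext)) / house.c
    return pd.DataFrame({"time": times, "temperature": temps, "power": powers})


@dataclass(frozen=True)
class TownSpec:
    """Recipe for the two-towns experiment.

    Heat-loss coefficients are log-normal (mean ``k_mean``, coefficient of
    variation ``k_cv``); thermostat set temperatures are normal (mean
    ``setpoint_mean``, CV ``setpoint_cv``) and drawn independently of k.
    Both towns share the radiator design and outdoor temperature.
    """

    n_houses: int = 500
    k_mean: float = 0.15
    k_cv: float = 0.3
    setpoint_mean: float = 21.0
    setpoint_cv: float = 0.05
    t_ext: float = 10.0
    radiator: Radiator = field(default_factory=Radiator)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_houses < 10:
            raise InputError(f"need >= 10 houses per town, got {self.n_houses}")
        if not self.k_mean > 0:
            raise InputError("k_mean must be > 0")
        for name in ("k_cv", "setpoint_cv"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


def _draw_k(spec: TownSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.k_cv == 0:
        return np.full(spec.n_houses, spec.k_mean)
    sigma = np.sqrt(np.log1p(spec.k_cv**2))
    mu = np.log(spec.k_mean) - sigma**2 / 2  # mean-parameterized log-normal
    return rng.lognormal(mu, sigma, size=spec.n_houses)


def simulate_town(spec: TownSpec, regime: str, rng: np.random.Generator) -> pd.DataFrame:
    """Steady states for one town of houses under one regulation regime."""
    k = _draw_k(spec, rng)
    if regime == THERMOSTAT:
        setpoints = rng.normal(
            spec.setpoint_mean, spec.setpoint_cv * spec.setpoint_mean, spec.n_houses
        )
    else:
        setpoints = np.full(spec.n_houses, np.nan)
    rows = []
    for i in range(spec.n_houses):
        house = House(
            k=float(k[i]),
            t_ext=spec.t_ext,
            regime=regime,
            radiator=spec.radiator,
            setpoint=None if regime == RADIATOR else float(setpoints[i]),
        )
        ss = steady_state(house)
        rows.append(
            {
                "house_id": i,
                "regime": regime,
                "k": float(k[i]),
                "setpoint": float(setpoints[i]),
                "T_steady": ss.temperature,
                "energy": ss.energy,
                "mode": ss.mode,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoTownsResult:
    r_thermostat: float
    r_radiator: float
    table: pd.DataFrame


def two_towns(spec: TownSpec) -> TwoTownsResult:
    """Temperature–energy Pearson correlation in each of the two towns.

    Under the stated premises (set temperatures independent of heat loss;
    most thermostat houses unsaturated) the thermostat town's coefficient is
    positive and the radiator town's negative.
    """
    rng = np.random.default_rng(spec.seed)
    thermo = simulate_town(spec, THERMOSTAT, rng)
    radiator = simulate_town(spec, RADIATOR, rng)
    rs = []
    for frame in (thermo, radiator):
        t, e = frame["T_steady"].to_numpy(), frame["energy"].to_numpy()
        if np.ptp(t) == 0 or np.ptp(e) == 0:
            raise UndefinedCorrelationError(
                "degenerate town: zero variance in temperature or energy"
            )
        rs.append(float(stats.pearsonr(t, e).statistic))
    table = pd.concat([thermo, radiator], ignore_index=True)
    return TwoTownsResult(r_thermostat=rs[0], r_radiator=rs[1], table=table)
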