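"""Synthetic cohorts under the two competing models of homeostatic regulation.

Equilibrium-point model
    Each individual owns a private parameterization of the feedback loop,
    drawn log-normally around a shared template; the individual's ambient
    (parameter, hormone) pair is the intersection point of their two curves.
    Inter-individual variation in ambient levels arises passively from
    variation in the loop components. With variation confined to the
    effector arm ("effector-dominant" — the empirically motivated regime:
    the hormone's response to the parameter is tightly conserved across
    individuals), every individual's point lies on the one shared sensor
    curve, so the cohort correlation sign equals the sensor direction and
    the Spearman correlation is exactly ±1.

Set-point model
    Each individual is assigned a target parameter level drawn independently
    of their effector sensitivity (targets are set "without regard to" the
    effector organ), and the controller adjusts the hormone to whatever
    level attains the target: ``H = g^{-1}(T)`` through that individual's
    effector curve. The cohort correlation sign then equals the effector
    direction — positive for calcium/PTH, negative for glucose/insulin —
    which is the prediction the empirical correlations contradict.

Parameter draws are log-normal with median equal to the template value:
``draw = template * exp(sigma * Z)`` with ``sigma^2 = ln(1 + CV^2)``, so the
draw mean is ``template * exp(sigma^2 / 2)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ModelError
from .feedback_core import (
    EffectorCurve,
    FeedbackSystem,
    SensorCurve,
    _solve_equilibria_bisect,
    predefined_system,
    solve_equilibrium,
)

__all__ = [
    "PopulationSpec",
    "Individual",
    "CohortSample",
    "sample_population",
    "simulate_equilibrium_cohort",
    "simulate_setpoint_cohort",
    "simulate_cohort",
]

EQUILIBRIUM = "equilibrium"
SETPOINT = "setpoint"
_MODELS = (EQUILIBRIUM, SETPOINT)
_MODES = ("effector_dominant", "sensor_dominant", "mixed")

_SENSOR_PARAMS = ("alpha", "beta")
_EFFECTOR_PARAMS = ("p0", "gain", "k")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one simulated cohort.

    Parameters
    ----------
    system
        Template feedback loop; individuals are drawn around it.
    n
        Cohort size (>= 2).
    seed
        RNG seed; the whole cohort is reproducible from it.
    model
        ``"equilibrium"`` or ``"setpoint"``.
    variation_mode
        ``"effector_dominant"`` (sensor CVs forced to 0, the default
        empirical regime), ``"sensor_dominant"`` (effector CVs 0) or
        ``"mixed"``.
    alpha_cv, beta_cv, p0_cv, gain_cv, k_cv
        Coefficient of variation of each curve parameter (0 <= CV < 1).
    setpoint_mean
        Mean of the target distribution (set-point model). ``None`` means
        "the template equilibrium parameter level".
    setpoint_cv
        CV of the target distribution.
    eps
        Truncation margin: targets are redrawn until inside
        ``(P0 + eps*G, P0 + (1-eps)*G)`` of the individual's effector, so
        the inversion is defined.
    """

    system: FeedbackSystem
    n: int
    seed: int
    model: str
    variation_mode: str = "effector_dominant"
    alpha_cv: float = 0.0
    beta_cv: float = 0.0
    p0_cv: float = 0.2
    gain_cv: float = 0.2
    k_cv: float = 0.2
    setpoint_mean: float | None = None
    setpoint_cv: float = 0.1
    eps: float = 0.05
    redraw_cap: int = 100
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError(f"n must be >= 2, got {self.n}")
        if self.model not in _MODELS:
            raise InputError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.variation_mode not in _MODES:
            raise InputError(
                f"variation_mode must be one of {_MODES}, got {self.variation_mode!r}"
            )
        for name in ("alpha_cv", "beta_cv", "p0_cv", "gain_cv", "k_cv", "setpoint_cv"):
            cv = getattr(self, name)
            if not 0.0 <= cv < 1.0:
                raise InputError(f"{name} must satisfy 0 <= CV < 1, got {cv}")
        if self.variation_mode == "effector_dominant" and (
            self.alpha_cv != 0.0 or self.beta_cv != 0.0
        ):
            raise InputError("effector_dominant mode requires sensor CVs of exactly 0")
        if self.variation_mode == "sensor_dominant" and (
            self.p0_cv != 0.0 or self.gain_cv != 0.0 or self.k_cv != 0.0
        ):
            raise InputError("sensor_dominant mode requires effector CVs of exactly 0")
        if not 0.0 < self.eps < 0.5:
            raise InputError(f"eps must be in (0, 0.5), got {self.eps}")

    @classmethod
    def for_system(cls, name: str, **kwargs) -> "PopulationSpec":
        """Spec around a predefined template (``calcium_pth``, ...)."""
        return cls(system=predefined_system(name), **kwargs)

    def to_dict(self) -> dict:
        block = dataclasses.asdict(self)
        block["system"] = self.system.to_dict()
        return block

    @classmethod
    def from_dict(cls, block: dict) -> "PopulationSpec":
        data = dict(block)
        data["system"] = FeedbackSystem.from_dict(data["system"])
        return cls(**data)


@dataclass(frozen=True)
class Individual:
    """One simulated person: an index plus their private loop parameters."""

    index: int
    system: FeedbackSystem


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def sample_population(spec: PopulationSpec) -> list[Individual]:
    """Draw ``spec.n`` individuals around the template.

    Each curve parameter with CV > 0 is drawn log-normally (median = template
    value); draws are independent across parameters and individuals, from a
    single generator seeded with ``spec.seed``. A parameter vector that
    violates the curve invariants is redrawn (bounded by ``spec.redraw_cap``).
    """
    rng = np.random.default_rng(spec.seed)
    draws = _draw_parameters(spec, rng)
    individuals = []
    for i in range(spec.n):
        individuals.append(Individual(index=i, system=_build_system(spec, draws, i)))
    return individuals


def _draw_parameters(spec: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    template = {
        "alpha": spec.system.sensor.alpha,
        "beta": spec.system.sensor.beta,
        "p0": spec.system.effector.p0,
        "gain": spec.system.effector.gain,
        "k": spec.system.effector.k,
    }
    cvs = {
        "alpha": spec.alpha_cv,
        "beta": spec.beta_cv,
        "p0": spec.p0_cv,
        "gain": spec.gain_cv,
        "k": spec.k_cv,
    }
    cols = {}
    for name in _SENSOR_PARAMS + _EFFECTOR_PARAMS:
        base, cv = template[name], cvs[name]
        if cv == 0.0:
            cols[name] = np.full(spec.n, base)
        else:
            sigma = _lognormal_sigma(cv)
            cols[name] = base * np.exp(sigma * rng.standard_normal(spec.n))
    frame = pd.DataFrame(cols)
    # Multiplicative draws preserve sign and positivity, so invariant
    # violations need degenerate templates; redraw defensively anyway.
    for name in ("beta", "gain", "k"):
        bad = ~(frame[name] > 0)
        tries = 0
        while bad.any():
            tries += 1
            if tries > spec.redraw_cap:
                raise ModelError(f"redraw cap exceeded for parameter {name!r}")
            sigma = _lognormal_sigma(cvs[name])
            frame.loc[bad, name] = template[name] * np.exp(
                sigma * rng.standard_normal(int(bad.sum()))
            )
            bad = ~(frame[name] > 0)
    return frame


def _build_system(spec: PopulationSpec, draws: pd.DataFrame, i: int) -> FeedbackSystem:
    row = draws.iloc[i]
    return FeedbackSystem(
        name=spec.system.name,
        sensor=SensorCurve(
            direction=spec.system.sensor.direction,
            alpha=float(row["alpha"]),
            beta=float(row["beta"]),
        ),
        effector=EffectorCurve(
            direction=spec.system.effector.direction,
            p0=float(row["p0"]),
            gain=float(row["gain"]),
            k=float(row["k"]),
        ),
        units_p=spec.system.units_p,
        units_h=spec.system.units_h,
    )


@dataclass(frozen=True)
class CohortSample:
    """Paired (parameter, hormone) values for one simulated cohort."""

    p: np.ndarray
    h: np.ndarray
    spec: PopulationSpec
    parameters: pd.DataFrame  # per-individual drawn curve parameters (audit)

    def __post_init__(self) -> None:
        if len(self.p) != self.spec.n or len(self.h) != self.spec.n:
            raise InputError("sample length must equal spec.n")
        if not (np.all(np.isfinite(self.p)) and np.all(np.isfinite(self.h))):
            raise InputError("all P, H must be finite")
        if np.any(self.p <= 0) or np.any(self.h <= 0):
            raise InputError("all P, H must be positive")

    def __len__(self) -> int:
        return self.spec.n

    @property
    def pairs(self) -> np.ndarray:
        return np.column_stack([self.p, self.h])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.spec.n),
                "P": self.p,
                "H": self.h,
                "model": self.spec.model,
                "seed": self.spec.seed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_equilibrium_cohort(spec: PopulationSpec) -> CohortSample:
    """Each individual's (P, H) is their own loop's intersection point.

    In effector-dominant mode all points fall exactly on the shared sensor
    curve, making the cohort's Spearman correlation ±1 with the sensor's
    sign.
    """
    if spec.model != EQUILIBRIUM:
        raise InputError(f"spec.model must be {EQUILIBRIUM!r}, got {spec.model!r}")
    individuals = sample_population(spec)
    systems = [ind.system for ind in individuals]
    try:
        p, h = _solve_equilibria_bisect(systems)
    except ModelError as exc:  # attach the offending index for diagnosis
        for ind in individuals:
            try:
                solve_equilibrium(ind.system, tolerance=spec.tolerance)
            except ModelError as inner:
                raise ModelError(f"individual {ind.index}: {inner}") from inner
        raise exc
    params = pd.DataFrame([_system_row(s) for s in systems])
    return CohortSample(p=p, h=h, spec=spec, parameters=params)


def simulate_setpoint_cohort(spec: PopulationSpec) -> CohortSample:
    """Each individual attains an independently drawn target exactly.

    The target T is drawn from a normal distribution (mean ``setpoint_mean``,
    CV ``setpoint_cv``) truncated to the individual's invertible range
    ``(P0 + eps*G, P0 + (1-eps)*G)``, statistically independent of the
    effector draws (exact inverse-CDF sampling of the truncated normal, so
    truncation cannot fail for tail individuals). The hormone is then the
    closed-form effector inverse ``H = g^{-1}(T)``.
    """
    if spec.model != SETPOINT:
        raise InputError(f"spec.model must be {SETPOINT!r}, got {spec.model!r}")
    rng = np.random.default_rng(spec.seed)
    draws = _draw_parameters(spec, rng)

    mean = spec.setpoint_mean
    if mean is None:
        mean = solve_equilibrium(spec.system, tolerance=spec.tolerance).p_star
    sd = spec.setpoint_cv * abs(mean)

    p0 = draws["p0"].to_numpy()
    gain = draws["gain"].to_numpy()
    lo = p0 + spec.eps * gain
    hi = p0 + (1.0 - spec.eps) * gain

    if sd == 0.0:
        targets = np.full(spec.n, mean)
        if np.any(targets <= lo) or np.any(targets >= hi):
            raise ModelError(
                "degenerate target distribution (CV = 0) outside an "
                "individual's invertible range"
            )
    else:
        cdf_lo = stats.norm.cdf(lo, loc=mean, scale=sd)
        cdf_hi = stats.norm.cdf(hi, loc=mean, scale=sd)
        mass = cdf_hi - cdf_lo
        if np.any(mass < 1e-12):
            raise ModelError(
                f"{int((mass < 1e-12).sum())} individual(s) have essentially "
                "no target mass inside the invertible range; widen eps or "
                "narrow setpoint_cv"
            )
        u = rng.uniform(cdf_lo, cdf_hi)
        targets = stats.norm.ppf(u, loc=mean, scale=sd)
        # keep strictly inside the open interval against rounding
        targets = np.clip(targets, np.nextafter(lo, hi), np.nextafter(hi, lo))

    k = draws["k"].to_numpy()
    if spec.system.effector.sign > 0:
        h = k * (targets - p0) / (p0 + gain - targets)
    else:
        h = k * (p0 + gain - targets) / (targets - p0)
    return CohortSample(p=targets, h=h, spec=spec, parameters=draws.copy())


def simulate_cohort(spec: PopulationSpec) -> CohortSample:
    """Dispatch on ``spec.model``."""
    if spec.model == EQUILIBRIUM:
        return simulate_equilibrium_cohort(spec)
    return simulate_setpoint_cohort(spec)


def _system_row(s: FeedbackSystem) -> dict:
    return {
        "alpha": s.sensor.alpha,
        "beta": s.sensor.beta,
        "p0": s.effector.p0,
        "gain": s.effector.gain,
        "k": s.effector.k,
    }
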