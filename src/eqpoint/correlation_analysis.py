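"""Cohort correlations and the sign test that separates the two models.

Under a set-point model the population correlation between a parameter and
its controlling hormone must run in the direction of the parameter's
response to the hormone (the effector direction): individuals with a higher
target can only attain it by running the hormone at the level that produces
it. Under an equilibrium-point model with variation concentrated in the
effector arm, the correlation instead runs along the shared sensor curve
(the hormone's response to the parameter). The two implied signs are
opposite for every negative-feedback loop, so a cohort's correlation sign is
evidence for one model against the other.

The packaged fixture (``data/table1.csv``) carries the ten published cohort
correlations this package evaluates: five calcium/PTH subgroups from two
studies and five glucose/insulin subgroups from three studies. Every one of
them runs with the sensor direction — negative for calcium/PTH, positive for
glucose/insulin — i.e. all ten contradict the set-point prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, InputError, UndefinedCorrelationError
from .feedback_core import PREDEFINED_DIRECTIONS, STIMULATORY, FeedbackSystem
from .population_models import EQUILIBRIUM, SETPOINT, CohortSample

__all__ = [
    "CorrelationRecord",
    "ConsistencyReport",
    "correlation",
    "implied_sign",
    "classify",
    "evaluate_table",
    "load_table1",
    "read_records_csv",
    "CONSISTENT",
    "INCONSISTENT",
    "INDETERMINATE",
]

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
INDETERMINATE = "indeterminate"

_MODELS = (EQUILIBRIUM, SETPOINT)
_METHODS = ("pearson", "spearman", "unspecified")
_TRANSFORMS = ("identity", "log")


@dataclass(frozen=True)
class CorrelationRecord:
    """One cohort-level parameter/hormone correlation, empirical or simulated."""

    system: str
    source: str
    subgroup: str
    n: int
    r: float
    method: str = "unspecified"
    hormone_transform: str = "identity"
    significance: str = ""

    def __post_init__(self) -> None:
        if self.system not in PREDEFINED_DIRECTIONS:
            raise ConfigError(
                f"unknown system {self.system!r}; known: {sorted(PREDEFINED_DIRECTIONS)}"
            )
        if not -1.0 <= self.r <= 1.0:
            raise InputError(f"|r| must be <= 1, got {self.r}")
        if self.n < 3:
            raise InputError(f"n must be >= 3, got {self.n}")
        if self.method not in _METHODS:
            raise InputError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.hormone_transform not in _TRANSFORMS:
            raise InputError(
                f"hormone_transform must be one of {_TRANSFORMS}, "
                f"got {self.hormone_transform!r}"
            )


def correlation(
    sample: Union[CohortSample, Sequence], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value for paired (P, H) data.

    Accepts a :class:`CohortSample` or any sequence of (P, H) pairs. The
    p-value comes from the t transform with n-2 degrees of freedom (Pearson)
    or the standard large-sample approximation (Spearman).
    """
    if isinstance(sample, CohortSample):
        x, y = sample.p, sample.h
    else:
        arr = np.asarray(sample, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InputError("pairs must be a sequence of (P, H) tuples")
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise InputError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a coordinate")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise InputError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(res.statistic), float(res.pvalue)


def implied_sign(system: Union[str, FeedbackSystem], model: str) -> int:
    """The correlation sign a regulation model forces on a population.

    set-point  -> sign of the effector direction (parameter's response to
                  the hormone): +1 calcium/PTH, -1 glucose/insulin, +1 FT4/TSH.
    equilibrium (effector-dominant variation) -> sign of the sensor direction
                  (hormone's response to the parameter): the opposite in
                  every negative loop.
    """
    if model not in _MODELS:
        raise InputError(f"model must be one of {_MODELS}, got {model!r}")
    if isinstance(system, FeedbackSystem):
        sensor_dir, effector_dir = system.sensor.direction, system.effector.direction
    else:
        if system not in PREDEFINED_DIRECTIONS:
            raise ConfigError(f"unknown system {system!r}")
        sensor_dir, effector_dir = PREDEFINED_DIRECTIONS[system]
    direction = effector_dir if model == SETPOINT else sensor_dir
    return +1 if direction == STIMULATORY else -1


def classify(record: CorrelationRecord, model: str) -> str:
    """Consistent / inconsistent / indeterminate under one regulation model.

    Classification is by point-estimate sign; an exact zero is indeterminate,
    never coerced. Significance labels are carried through reports but do not
    alter the classification (non-significant rows still count).
    """
    if record.r == 0.0:
        return INDETERMINATE
    expected = implied_sign(record.system, model)
    observed = 1 if record.r > 0 else -1
    return CONSISTENT if observed == expected else INCONSISTENT


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-record classifications and aggregate counts under both models."""

    records: tuple[CorrelationRecord, ...]
    classifications: dict  # model -> tuple of per-record labels
    counts: dict  # model -> {consistent, inconsistent, indeterminate}
    implied_signs: dict  # system -> {model: sign}

    def __post_init__(self) -> None:
        for model, tally in self.counts.items():
            if sum(tally.values()) != len(self.records):
                raise InputError(f"counts for {model!r} do not sum to record count")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.records):
            rows.append(
                {
                    "system": rec.system,
                    "source": rec.source,
                    "subgroup": rec.subgroup,
                    "n": rec.n,
                    "r": rec.r,
                    "significance": rec.significance,
                    "setpoint": self.classifications[SETPOINT][i],
                    "equilibrium": self.classifications[EQUILIBRIUM][i],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_records": len(self.records),
            "counts": self.counts,
            "implied_signs": self.implied_signs,
            "records": self.to_frame().to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [f"{len(self.records)} correlation records"]
        for model in _MODELS:
            tally = self.counts[model]
            lines.append(
                f"  {model:>11}-model: {tally[CONSISTENT]} consistent, "
                f"{tally[INCONSISTENT]} inconsistent, "
                f"{tally[INDETERMINATE]} indeterminate"
            )
        lines.append("implied signs:")
        for system, signs in sorted(self.implied_signs.items()):
            lines.append(
                f"  {system}: setpoint "
                f"{'>0' if signs[SETPOINT] > 0 else '<0'} / equilibrium "
                f"{'>0' if signs[EQUILIBRIUM] > 0 else '<0'}"
            )
        return "\n".join(lines)


def evaluate_table(records: Iterable[CorrelationRecord]) -> ConsistencyReport:
    """Classify every record under both models and tally the counts."""
    records = tuple(records)
    if not records:
        raise InputError("need at least one correlation record")
    classifications = {
        model: tuple(classify(rec, model) for rec in records) for model in _MODELS
    }
    counts = {
        model: {
            label: labels.count(label)
            for label in (CONSISTENT, INCONSISTENT, INDETERMINATE)
        }
        for model, labels in classifications.items()
    }
    systems = sorted({rec.system for rec in records})
    implied = {
        system: {model: implied_sign(system, model) for model in _MODELS}
        for system in systems
    }
    return ConsistencyReport(
        records=records,
        classifications=classifications,
        counts=counts,
        implied_signs=implied,
    )


def read_records_csv(path) -> list[CorrelationRecord]:
    """Read correlation records from CSV (columns: system, source, subgroup,
    n, r, method, transform, significance)."""
    path = Path(path)
    if not path.exists():
        raise DataError(
            f"correlation table not found: {path} "
            "(the packaged fixture is available via load_table1())"
        )
    frame = pd.read_csv(path)
    required = {"system", "source", "subgroup", "n", "r"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"correlation table missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            CorrelationRecord(
                system=str(row["system"]),
                source=str(row["source"]),
                subgroup=str(row["subgroup"]),
                n=int(row["n"]),
                r=float(row["r"]),
                method=str(row.get("method", "unspecified")),
                hormone_transform=str(row.get("transform", "identity")),
                significance=str(row.get("significance", "")),
            )
        )
    return records


def load_table1() -> list[CorrelationRecord]:
    """The ten published cohort correlations bundled with the package."""
    with resources.as_file(
        resources.files("eqpoint.data").joinpath("table1.csv")
    ) as path:
        return read_records_csv(path)
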