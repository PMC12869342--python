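"""Health states, transition matrices, life tables, and run configuration.

The disease model has four health states: three alive severity states
(mild, moderate, severe — defined by cut points on an 11-point pain scale)
plus an absorbing dead state. Annual transition probabilities among the
alive states are strategy-specific and conditional on surviving the cycle;
background mortality comes from an age- and sex-specific life table and is
applied uniformly across alive states.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Alive severity states, in fixed model order.
ALIVE_STATES: tuple[str, ...] = ("mild", "moderate", "severe")
DEAD: str = "dead"
#: All four health states; the dead state is absorbing.
STATES: tuple[str, ...] = ALIVE_STATES + (DEAD,)

#: Inclusive pain-score intervals on the 0-10 numeric rating scale.
PAIN_RANGES: dict[str, tuple[int, int] | None] = {
    "mild": (0, 3),
    "moderate": (4, 6),
    "severe": (7, 10),
    "dead": None,
}

ROW_SUM_TOL = 1e-9
#: Internal hard cap on the number of annual cycles; a run that has not
#: extinguished by then is treated as non-terminating.
HARD_CYCLE_CAP = 200

SEXES = ("female", "male")


@dataclass(frozen=True)
class HealthState:
    """One model health state and its pain-scale definition."""

    label: str
    pain_range: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ValidationError(f"unknown health state {self.label!r}")
        if self.pain_range != PAIN_RANGES[self.label]:
            raise ValidationError(
                f"pain range {self.pain_range} inconsistent with state {self.label!r}"
            )

    @property
    def is_absorbing(self) -> bool:
        return self.label == DEAD


def health_states() -> tuple[HealthState, ...]:
    """The four model states in canonical order."""
    return tuple(HealthState(s, PAIN_RANGES[s]) for s in STATES)


class DiseaseTransitionMatrix:
    """Annual transition probabilities among alive states for one strategy.

    Probabilities are conditional on surviving the cycle; each row must sum
    to 1 within ``ROW_SUM_TOL``. Row/column order is ``ALIVE_STATES``.
    """

    __slots__ = ("strategy", "probs")

    def __init__(self, strategy: str, probs) -> None:
        arr = np.asarray(probs, dtype=float).copy()
        if arr.shape != (3, 3):
            raise ValidationError(
                f"transition matrix for {strategy!r} must be 3x3, got {arr.shape}"
            )
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValidationError(
                f"transition matrix for {strategy!r} has entries outside [0, 1]"
            )
        sums = arr.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > ROW_SUM_TOL:
                raise ValidationError(
                    f"transition row {ALIVE_STATES[i]!r} for strategy {strategy!r} "
                    f"sums to {s:.10g}, expected 1"
                )
        arr.flags.writeable = False
        object.__setattr__(self, "strategy", strategy)
        object.__setattr__(self, "probs", arr)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("DiseaseTransitionMatrix is immutable")

    def prob(self, from_state: str, to_state: str) -> float:
        return float(
            self.probs[ALIVE_STATES.index(from_state), ALIVE_STATES.index(to_state)]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiseaseTransitionMatrix({self.strategy!r})"


class LifeTable:
    """Age- and sex-specific annual death probabilities (qx).

    Ages must be contiguous per sex, start at or below 18, and share the
    same range for both sexes. Under strict validation the terminal age
    must carry qx = 1 (a closed table); pass ``validate=False`` to build
    deliberately open tables (e.g. zero-mortality test tables).
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True) -> None:
        required = {"age", "sex", "qx"}
        if not required.issubset(table.columns):
            raise ValidationError(
                f"life table needs columns {sorted(required)}, got {list(table.columns)}"
            )
        tab = table[["age", "sex", "qx"]].copy()
        tab["age"] = tab["age"].astype(int)
        if not set(tab["sex"]) <= set(SEXES):
            raise ValidationError(f"life table sex values must be in {SEXES}")
        if tab["qx"].lt(0).any() or tab["qx"].gt(1).any():
            raise ValidationError("life table qx values must lie in [0, 1]")
        self._qx: dict[str, np.ndarray] = {}
        ranges = {}
        for sex, grp in tab.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if len(ages) == 0:
                raise ValidationError(f"life table has no rows for sex {sex!r}")
            if ages[0] != ages.min() or np.any(np.diff(ages) != 1):
                raise ValidationError(f"life table ages for {sex!r} are not contiguous")
            ranges[sex] = (int(ages[0]), int(ages[-1]))
            self._qx[sex] = grp["qx"].to_numpy(dtype=float)
        if set(ranges) != set(SEXES):
            raise ValidationError("life table must contain both sexes")
        if len(set(ranges.values())) != 1:
            raise ValidationError("life table age ranges differ between sexes")
        self.min_age, self.max_age = ranges["female"]
        if validate:
            if self.min_age > 18:
                raise ValidationError(
                    f"life table must start at age <= 18, starts at {self.min_age}"
                )
            for sex in SEXES:
                if self._qx[sex][-1] != 1.0:
                    raise ValidationError(
                        f"life table terminal qx for {sex!r} must be 1"
                    )
        self._frame = tab.sort_values(["sex", "age"]).reset_index(drop=True)

    def qx(self, age: int, sex: str) -> float:
        """Annual death probability at `age`, clamped to the terminal row above."""
        if sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        if age < self.min_age:
            raise ValidationError(
                f"age {age} below life-table minimum {self.min_age}"
            )
        idx = min(int(age), self.max_age) - self.min_age
        return float(self._qx[sex][idx])

    def qx_array(self, ages: np.ndarray, sex: str) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        if np.any(ages < self.min_age):
            bad = int(ages[ages < self.min_age][0])
            raise ValidationError(f"age {bad} below life-table minimum {self.min_age}")
        idx = np.minimum(ages, self.max_age) - self.min_age
        return self._qx[sex][idx]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, validate: bool = True) -> "LifeTable":
        return cls(frame, validate=validate)


@dataclass(frozen=True)
class CohortSpec:
    """Demographics of the entering cohort.

    The cohort enters in the moderate or severe state. Age heterogeneity is
    handled by discretizing a truncated normal age distribution into
    integer-age strata; each stratum ages one year per cycle. Sex enters the
    model only through the background-mortality mix.
    """

    mean_age: float = 48.4
    sd_age: float = 10.4
    prop_female: float = 0.944
    initial_state_split: tuple[float, float] = (0.5, 0.5)  # (moderate, severe)
    age_bounds: tuple[int, int] = (18, 90)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValidationError("prop_female must lie in [0, 1]")
        pm, ps = self.initial_state_split
        if pm < 0 or ps < 0 or abs(pm + ps - 1.0) > 1e-9:
            raise ValidationError(
                "initial_state_split must be nonnegative and sum to 1 "
                "(all mass on moderate/severe)"
            )
        lo, hi = self.age_bounds
        if not lo <= self.mean_age <= hi:
            raise ValidationError(
                f"mean_age {self.mean_age} outside age bounds {self.age_bounds}"
            )
        if self.sd_age < 0:
            raise ValidationError("sd_age must be nonnegative")

    def age_strata(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer entry ages and their probability weights (sum to 1)."""
        lo, hi = self.age_bounds
        if self.sd_age == 0:
            return np.array([int(round(self.mean_age))]), np.array([1.0])
        ages = np.arange(lo, hi + 1)
        dist = stats.norm(self.mean_age, self.sd_age)
        mass = dist.cdf(ages + 0.5) - dist.cdf(ages - 0.5)
        total = mass.sum()
        if total <= 0:
            raise ValidationError("age distribution places no mass inside age bounds")
        return ages, mass / total


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: discounting, perspective, stopping rule.

    The horizon is lifetime: cycles continue until the alive fraction drops
    to ``extinction_epsilon`` or every age stratum has passed ``max_age``
    (death is forced at ``max_age``). ``max_cycles`` optionally truncates the
    horizon, mainly for tests and diagnostics.
    """

    discount_rate: float = 0.03
    cycle_length: float = 1.0  # years; the model is annual-cycle only
    wtp_thresholds: tuple[float, ...] = (50_000.0, 100_000.0, 150_000.0)
    perspective: str = "payer"
    extinction_epsilon: float = 1e-7
    max_age: int = 100
    half_cycle: bool = True
    max_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be nonnegative")
        if self.cycle_length != 1.0:
            raise ValidationError("only annual cycles (cycle_length=1) are supported")
        wtps = tuple(float(w) for w in self.wtp_thresholds)
        if any(w <= 0 for w in wtps) or list(wtps) != sorted(wtps):
            raise ValidationError("wtp_thresholds must be positive and ascending")
        object.__setattr__(self, "wtp_thresholds", wtps)
        if self.perspective not in ("payer", "societal"):
            raise ValidationError(
                f"perspective must be 'payer' or 'societal', got {self.perspective!r}"
            )
        if not 0.0 < self.extinction_epsilon <= 1e-3:
            raise ValidationError("extinction_epsilon must lie in (0, 1e-3]")
        if self.max_cycles is not None and not 1 <= self.max_cycles <= HARD_CYCLE_CAP:
            raise ValidationError(
                f"max_cycles must lie in [1, {HARD_CYCLE_CAP}]"
            )

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)
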