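"""Markov cohort engine: annual-cycle propagation with background mortality.

The cohort is represented as weighted integer-age strata. Every stratum
starts from the same severity split, ages one year per cycle, and faces its
own age-specific death probability; death is forced at the configured
maximum age. Because mortality does not depend on the severity state, the
strategy's 3x3 disease matrix acts on the severity distribution while the
life table drains mass into the absorbing dead state.

Half-cycle correction is trapezoidal: the person-year weight credited to
cycle t is the average of the start-of-cycle and end-of-cycle alive-state
occupancies, the standard life-table treatment of mid-cycle transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .states import (
    ALIVE_STATES,
    HARD_CYCLE_CAP,
    CohortSpec,
    DiseaseTransitionMatrix,
    LifeTable,
    ModelConfig,
)

__all__ = [
    "discount_factor",
    "mortality_probability",
    "build_cycle_matrix",
    "run_cohort",
    "CohortTrace",
    "MortalityGrid",
]


def discount_factor(t, r: float):
    """Discrete annual discount weight (1+r)^(-t) for cycle index t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("cycle index must be nonnegative")
    if r < 0:
        raise ValidationError("discount rate must be nonnegative")
    out = (1.0 + r) ** (-t)
    return float(out) if out.ndim == 0 else out


def mortality_probability(age: int, prop_female: float, life_table: LifeTable) -> float:
    """Sex-mixed annual death probability at `age`.

    Returns prop_female * qx(age, female) + (1 - prop_female) * qx(age, male),
    with ages above the table's terminal row clamped to it.
    """
    if not 0.0 <= prop_female <= 1.0:
        raise ValidationError("prop_female must lie in [0, 1]")
    qf = life_table.qx(age, "female")
    qm = life_table.qx(age, "male")
    return prop_female * qf + (1.0 - prop_female) * qm


def build_cycle_matrix(disease: DiseaseTransitionMatrix, p_death: float) -> np.ndarray:
    """Full 4x4 annual transition matrix for one cycle.

    The alive->alive block is the disease matrix scaled by the survival
    probability; every alive state shares the same death probability and the
    dead state is absorbing.
    """
    if not 0.0 <= p_death <= 1.0:
        raise ValidationError(f"p_death {p_death} outside [0, 1]")
    m = np.zeros((4, 4))
    m[:3, :3] = disease.probs * (1.0 - p_death)
    m[:3, 3] = p_death
    m[3, 3] = 1.0
    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-12):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"cycle matrix row {bad} sums to {sums[bad]:.15g}, expected 1"
        )
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over cycles plus half-cycle-corrected alive weights.

    ``occupancy`` has shape (T+1, 4) — cohort fractions over
    (mild, moderate, severe, dead) at the start of cycles 0..T.
    ``effective_occupancy`` has shape (T, 3): the alive-state person-year
    weights credited to cycles 0..T-1 (trapezoidal when half-cycle
    correction is on, start-of-cycle occupancy otherwise).
    """

    strategy: str
    occupancy: np.ndarray
    effective_occupancy: np.ndarray
    cycles_run: int

    def __post_init__(self) -> None:
        occ = self.occupancy
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("occupancy rows must each sum to 1")
        if np.any(np.diff(occ[:, 3]) < -1e-12):
            raise ValidationError("dead fraction must be nondecreasing")

    @property
    def alive_fraction(self) -> np.ndarray:
        return self.occupancy[:, :3].sum(axis=1)

    def person_years(self, r: float = 0.0) -> float:
        """Discounted alive person-years accumulated by the cohort."""
        T = self.effective_occupancy.shape[0]
        return float(
            discount_factor(np.arange(T), r) @ self.effective_occupancy.sum(axis=1)
        )


class MortalityGrid:
    """Precomputed per-stratum death probabilities for every cycle.

    Shared across strategies and PSA draws: background mortality depends
    only on age, sex mix, and the life table.
    """

    def __init__(self, cohort: CohortSpec, life_table: LifeTable, config: ModelConfig):
        ages, weights = cohort.age_strata()
        horizon = max(int(config.max_age) - int(ages.min()), 0) + 1
        grid = np.empty((len(ages), horizon))
        for t in range(horizon):
            at = ages + t
            q = (
                cohort.prop_female * life_table.qx_array(np.minimum(at, life_table.max_age), "female")
                + (1.0 - cohort.prop_female)
                * life_table.qx_array(np.minimum(at, life_table.max_age), "male")
            )
            grid[:, t] = np.where(at >= config.max_age, 1.0, q)
        if np.any(ages < life_table.min_age):
            raise ValidationError(
                f"entry age {int(ages.min())} below life-table minimum {life_table.min_age}"
            )
        self.ages = ages
        self.weights = weights
        self.p_death = grid

    def p_death_at(self, t: int) -> np.ndarray:
        if t < self.p_death.shape[1]:
            return self.p_death[:, t]
        return np.ones(len(self.ages))


def run_cohort(
    disease: DiseaseTransitionMatrix,
    cohort: CohortSpec,
    life_table: LifeTable,
    config: ModelConfig,
    grid: MortalityGrid | None = None,
) -> CohortTrace:
    """Propagate the cohort until extinction (or the configured cycle cap).

    Each age stratum is propagated with its own age-specific cycle matrix and
    the strata are aggregated by their probability weights. Stops at the
    first cycle where the aggregate alive fraction is at or below
    ``config.extinction_epsilon``, when ``config.max_cycles`` is reached, or
    errors out at the internal hard cap.
    """
    if grid is None:
        grid = MortalityGrid(cohort, life_table, config)
    pm, ps = cohort.initial_state_split
    S = len(grid.ages)
    alive = np.tile([0.0, pm, ps], (S, 1))  # per-stratum severity occupancy
    dead = np.zeros(S)
    P = disease.probs
    w = grid.weights
    occ_rows = []
    t = 0
    while True:
        agg_alive = w @ alive
        occ_rows.append(np.append(agg_alive, w @ dead))
        if agg_alive.sum() <= config.extinction_epsilon:
            break
        if config.max_cycles is not None and t >= config.max_cycles:
            break
        if t >= HARD_CYCLE_CAP:
            raise ValidationError(
                f"cohort not extinct after {HARD_CYCLE_CAP} cycles; "
                "extinction_epsilon unreachable for these inputs"
            )
        p_d = grid.p_death_at(t)
        dead = dead + alive.sum(axis=1) * p_d
        alive = (alive @ P) * (1.0 - p_d)[:, None]
        t += 1
    occupancy = np.array(occ_rows)
    T = occupancy.shape[0] - 1
    if config.half_cycle:
        eff = 0.5 * (occupancy[:-1, :3] + occupancy[1:, :3])
    else:
        eff = occupancy[:-1, :3].copy()
    return CohortTrace(
        strategy=disease.strategy,
        occupancy=occupancy,
        effective_occupancy=eff,
        cycles_run=T,
    )
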