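"""Cost-effectiveness economics: accrual, ICER, iNMB, dominance, frontier.

Lifetime discounted costs and QALYs per strategy are the atoms of the
analysis. Comparative statistics follow the standard decision rules:

* ICER between two strategies is incremental cost per incremental QALY.
* Incremental net monetary benefit at a willingness-to-pay threshold W is
  iNMB = W * dQALY - dCost.
* The efficiency frontier orders strategies by cost, removes strongly
  dominated options (another strategy is at least as cheap and at least as
  effective, strictly better on one axis), then iteratively removes
  extendedly dominated options until adjacent ICERs increase strictly.

Rounding (nearest dollar for money, 2-3 decimals for QALYs) is a display
convention only; all arithmetic here is full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import UndefinedICERError, ValidationError
from .markov import CohortTrace, discount_factor
from .states import ALIVE_STATES, ModelConfig

__all__ = [
    "StateEconomics",
    "StrategyOutcome",
    "NMBRecord",
    "FrontierResult",
    "accrue_outcomes",
    "icer",
    "inmb",
    "build_frontier",
    "frontier_nmb_oracle",
]

PERSPECTIVES = ("payer", "societal")

ON_FRONTIER = "on_frontier"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class StateEconomics:
    """Per-state utilities and annual costs, plus one strategy's drug cost.

    ``indirect`` holds annualized indirect (societal) costs and may be None
    when only the payer perspective is analyzed. ``ordered=True`` enforces
    the severity ordering utilities(mild) >= utilities(moderate) >=
    utilities(severe), which generated inputs must satisfy.
    """

    strategy: str
    utilities: Mapping[str, float]
    direct_medical: Mapping[str, float]
    direct_nonmedical: Mapping[str, float]
    indirect: Mapping[str, float] | None
    drug_cost: float
    ordered: bool = True

    def __post_init__(self) -> None:
        for name, table in (
            ("utilities", self.utilities),
            ("direct_medical", self.direct_medical),
            ("direct_nonmedical", self.direct_nonmedical),
        ):
            missing = set(ALIVE_STATES) - set(table)
            if missing:
                raise ValidationError(f"{name} missing states {sorted(missing)}")
        for s in ALIVE_STATES:
            u = self.utilities[s]
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"utility for {s!r} is {u}, outside [0, 1]")
        cost_tables = [self.direct_medical, self.direct_nonmedical]
        if self.indirect is not None:
            if set(ALIVE_STATES) - set(self.indirect):
                raise ValidationError("indirect costs missing a state")
            cost_tables.append(self.indirect)
        for table in cost_tables:
            for s in ALIVE_STATES:
                if table[s] < 0:
                    raise ValidationError(f"negative cost for state {s!r}")
        if self.drug_cost < 0:
            raise ValidationError("drug_cost must be nonnegative")
        if self.ordered:
            u = [self.utilities[s] for s in ALIVE_STATES]
            if not (u[0] >= u[1] >= u[2]):
                raise ValidationError(
                    "utilities must be ordered mild >= moderate >= severe"
                )

    def annual_cost_vector(self, perspective: str) -> np.ndarray:
        """Total annual cost per alive state under the given perspective."""
        if perspective not in PERSPECTIVES:
            raise ValidationError(f"unknown perspective {perspective!r}")
        total = np.array(
            [
                self.direct_medical[s] + self.direct_nonmedical[s] + self.drug_cost
                for s in ALIVE_STATES
            ]
        )
        if perspective == "societal":
            if self.indirect is None:
                raise ValidationError(
                    "societal perspective requested but indirect costs are absent"
                )
            total = total + np.array([self.indirect[s] for s in ALIVE_STATES])
        return total

    def utility_vector(self) -> np.ndarray:
        return np.array([self.utilities[s] for s in ALIVE_STATES])


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected lifetime discounted cost and QALYs for one strategy."""

    strategy: str
    expected_cost: float
    expected_qaly: float
    perspective: str

    def __post_init__(self) -> None:
        if self.expected_cost < 0 or self.expected_qaly < 0:
            raise ValidationError("expected cost and QALYs must be nonnegative")
        if self.perspective not in PERSPECTIVES:
            raise ValidationError(f"unknown perspective {self.perspective!r}")


@dataclass(frozen=True)
class NMBRecord:
    """Incremental net monetary benefit of one strategy against a reference."""

    strategy: str
    reference: str
    wtp: float
    inmb: float


def accrue_outcomes(
    trace: CohortTrace,
    econ: StateEconomics,
    perspective: str | None = None,
    config: ModelConfig | None = None,
) -> StrategyOutcome:
    """Discounted lifetime cost and QALY accrual for one strategy's trace.

    QALYs are the discounted sum over cycles of the half-cycle-corrected
    alive occupancies weighted by state utilities; costs are analogous with
    the perspective-appropriate per-state annual cost (direct medical +
    direct nonmedical + drug acquisition, plus indirect under the societal
    perspective).
    """
    if config is None:
        config = ModelConfig()
    if perspective is None:
        perspective = config.perspective
    if trace.strategy != econ.strategy:
        raise ValidationError(
            f"trace is for {trace.strategy!r} but economics for {econ.strategy!r}"
        )
    eff = trace.effective_occupancy
    df = discount_factor(np.arange(eff.shape[0]), config.discount_rate)
    qaly = float(df @ (eff @ econ.utility_vector()))
    cost = float(df @ (eff @ econ.annual_cost_vector(perspective)))
    return StrategyOutcome(trace.strategy, cost, qaly, perspective)


def _check_pair(candidate: StrategyOutcome, reference: StrategyOutcome) -> None:
    if candidate.perspective != reference.perspective:
        raise ValidationError(
            "candidate and reference outcomes are from different perspectives"
        )


def icer(candidate: StrategyOutcome, reference: StrategyOutcome) -> float:
    """Incremental cost-effectiveness ratio, dollars per QALY (unrounded)."""
    _check_pair(candidate, reference)
    dq = candidate.expected_qaly - reference.expected_qaly
    if dq == 0.0:
        raise UndefinedICERError(
            f"ICER undefined: {candidate.strategy!r} and {reference.strategy!r} "
            "have equal QALYs; classify via dominance instead"
        )
    return (candidate.expected_cost - reference.expected_cost) / dq


def inmb(candidate: StrategyOutcome, reference: StrategyOutcome, wtp: float) -> NMBRecord:
    """Incremental net monetary benefit wtp*dQALY - dCost (unrounded)."""
    _check_pair(candidate, reference)
    if wtp < 0:
        raise ValidationError("willingness-to-pay threshold must be nonnegative")
    value = wtp * (candidate.expected_qaly - reference.expected_qaly) - (
        candidate.expected_cost - reference.expected_cost
    )
    return NMBRecord(candidate.strategy, reference.strategy, wtp, value)


@dataclass(frozen=True)
class FrontierResult:
    """Classification of every strategy plus the efficient frontier.

    ``frontier`` lists on-frontier strategies by ascending cost;
    ``frontier_icers`` maps each frontier strategy to its ICER against the
    previous distinct frontier point (None for the cheapest point and for a
    strategy exactly tied with its predecessor).
    """

    status: Mapping[str, str]
    frontier: tuple[str, ...]
    frontier_icers: Mapping[str, float | None]

    def strategies_with(self, status: str) -> tuple[str, ...]:
        return tuple(s for s, st in self.status.items() if st == status)


def build_frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Classify strategies by dominance and build the efficiency frontier.

    Strong dominance: some other strategy costs no more and yields no fewer
    QALYs, with at least one strict inequality (equal cost *and* equal QALYs
    dominate neither way; both survive). Extended dominance: among the
    survivors ordered by cost, any strategy whose adjacent ICER is not
    strictly below the next adjacent ICER is removed, repeating until the
    ICER sequence strictly increases.
    """
    if len(outcomes) == 0:
        raise ValidationError("at least one outcome is required")
    names = [o.strategy for o in outcomes]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate strategy names in outcomes")
    if len({o.perspective for o in outcomes}) > 1:
        raise ValidationError("outcomes mix perspectives")

    status: dict[str, str] = {}
    for o in outcomes:
        dominated = any(
            (p.expected_cost <= o.expected_cost)
            and (p.expected_qaly >= o.expected_qaly)
            and (
                p.expected_cost < o.expected_cost
                or p.expected_qaly > o.expected_qaly
            )
            for p in outcomes
            if p is not o
        )
        if dominated:
            status[o.strategy] = STRONGLY_DOMINATED

    survivors = [o for o in outcomes if o.strategy not in status]
    survivors.sort(key=lambda o: (o.expected_cost, -o.expected_qaly, o.strategy))

    # Collapse exact (cost, qaly) ties into single frontier points.
    points: list[list[StrategyOutcome]] = []
    for o in survivors:
        if points and (
            o.expected_cost == points[-1][0].expected_cost
            and o.expected_qaly == points[-1][0].expected_qaly
        ):
            points[-1].append(o)
        else:
            points.append([o])

    def adjacent_icers(pts: list[list[StrategyOutcome]]) -> list[float]:
        return [icer(pts[i + 1][0], pts[i][0]) for i in range(len(pts) - 1)]

    while True:
        if len(points) <= 2:
            break
        icers = adjacent_icers(points)
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                for o in points[i + 1]:
                    status[o.strategy] = EXTENDEDLY_DOMINATED
                del points[i + 1]
                removed = True
                break
        if not removed:
            break

    frontier: list[str] = []
    frontier_icers: dict[str, float | None] = {}
    for i, group in enumerate(points):
        for j, o in enumerate(group):
            status[o.strategy] = ON_FRONTIER
            frontier.append(o.strategy)
            if i == 0 or j > 0:
                frontier_icers[o.strategy] = None
            else:
                frontier_icers[o.strategy] = icer(o, points[i - 1][0])
    ordered_status = {o.strategy: status[o.strategy] for o in outcomes}
    return FrontierResult(ordered_status, tuple(frontier), frontier_icers)


def frontier_nmb_oracle(
    outcomes: Sequence[StrategyOutcome], wtp_grid: Iterable[float]
) -> dict[float, str]:
    """Brute-force verifier: the NMB-optimal strategy at each WTP.

    At each threshold returns the strategy maximizing wtp*QALY - cost (ties
    broken toward lower cost, then name). Every strategy optimal somewhere
    on a dense grid, plus the cheapest strategy (the wtp -> 0 limit), must
    lie on the efficiency frontier.
    """
    grid = [float(w) for w in wtp_grid]
    if len(grid) == 0:
        raise ValidationError("wtp grid must be non-empty")
    if grid != sorted(grid):
        raise ValidationError("wtp grid must be ascending")
    ordered = sorted(outcomes, key=lambda o: o.strategy)
    out: dict[float, str] = {}
    for w in grid:
        best = max(
            ordered,
            key=lambda o: (w * o.expected_qaly - o.expected_cost, -o.expected_cost),
        )
        out[w] = best.strategy
    return out
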