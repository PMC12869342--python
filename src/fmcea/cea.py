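"""Model/Results layer: build the analysis, fit it, summarize it.

``MarkovCEA`` is the modelling object: construct it from a
:class:`~fmcea.inputs.ModelInputs` bundle (or an input directory), call
``fit()`` for the deterministic base case, ``psa()`` for probabilistic
sensitivity analysis, ``one_way()`` for the tornado. ``fit()`` returns a
``CEAResults`` carrying per-strategy lifetime outcomes, the efficiency
frontier, iNMB at each willingness-to-pay threshold, and a ``summary()``
table shaped like the standard base-case table of a cost-effectiveness
report.

``evaluate_outcomes`` runs the same comparative layer directly on
externally supplied (cost, QALY) pairs — e.g. published tables — skipping
the Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import (
    EXTENDEDLY_DOMINATED,
    ON_FRONTIER,
    STRONGLY_DOMINATED,
    FrontierResult,
    NMBRecord,
    StrategyOutcome,
    build_frontier,
    frontier_nmb_oracle,
    inmb,
)
from .errors import ValidationError
from .inputs import ModelInputs
from .uncertainty import (
    CEACCurve,
    PSAResult,
    TornadoEntry,
    ceac,
    default_ranges,
    one_way_sensitivity,
    run_psa,
)

__all__ = ["MarkovCEA", "CEAResults", "PSAResults", "evaluate_outcomes"]


class MarkovCEA:
    """Markov cohort cost-effectiveness model over a set of strategies."""

    def __init__(self, inputs: ModelInputs, specs=None) -> None:
        self.inputs = inputs
        self.specs = specs or {}

    @classmethod
    def from_directory(cls, directory) -> "MarkovCEA":
        from .io import read_inputs

        inputs, specs = read_inputs(directory)
        return cls(inputs, specs)

    @property
    def strategies(self) -> tuple[str, ...]:
        return self.inputs.strategies

    def fit(
        self,
        perspective: str | None = None,
        reference: str | None = None,
    ) -> "CEAResults":
        """Run every strategy through the Markov + accrual pipeline."""
        if perspective is None:
            perspective = self.inputs.config.perspective
        outcomes = self.inputs.run_all(perspective)
        return evaluate_outcomes(
            outcomes,
            wtps=self.inputs.config.wtp_thresholds,
            reference=reference,
        )

    def psa(
        self,
        n_draws: int = 1000,
        seed: int = 20240101,
        perspective: str | None = None,
        specs=None,
    ) -> "PSAResults":
        """Second-order Monte Carlo; requires distribution specs."""
        use = specs if specs is not None else self.specs
        if not use:
            raise ValidationError(
                "PSA requires distribution specs (none attached to this model)"
            )
        raw = run_psa(self.inputs, use, n_draws, seed, perspective)
        return PSAResults(raw, self.inputs.config.wtp_thresholds)

    def one_way(
        self,
        candidate: str,
        reference: str,
        wtp: float,
        param_ranges: Mapping[str, tuple[float, float]] | None = None,
        perspective: str | None = None,
    ) -> list[TornadoEntry]:
        """One-way DSA; defaults to +/-20% ranges over every parameter."""
        if param_ranges is None:
            param_ranges = default_ranges(self.inputs.to_flat())
        return one_way_sensitivity(
            self.inputs, param_ranges, (candidate, reference), wtp, perspective
        )


def evaluate_outcomes(
    outcomes: Sequence[StrategyOutcome],
    wtps: Sequence[float] = (50_000.0, 100_000.0, 150_000.0),
    reference: str | None = None,
) -> "CEAResults":
    """Comparative analysis of precomputed lifetime outcomes.

    ``reference`` defaults to the least costly strategy; published tables
    typically fix it to the standard-of-care comparator instead.
    """
    names = [o.strategy for o in outcomes]
    if reference is None:
        reference = min(outcomes, key=lambda o: (o.expected_cost, o.strategy)).strategy
    if reference not in names:
        raise ValidationError(f"reference strategy {reference!r} not among outcomes")
    frontier = build_frontier(outcomes)
    ref_outcome = next(o for o in outcomes if o.strategy == reference)
    records = [
        inmb(o, ref_outcome, w) for o in outcomes for w in wtps
    ]
    return CEAResults(
        outcomes=tuple(outcomes),
        frontier=frontier,
        reference=reference,
        wtps=tuple(float(w) for w in wtps),
        inmb_records=tuple(records),
    )


@dataclass(frozen=True)
class CEAResults:
    """Base-case results: outcomes, frontier classification, iNMB table."""

    outcomes: tuple[StrategyOutcome, ...]
    frontier: FrontierResult
    reference: str
    wtps: tuple[float, ...]
    inmb_records: tuple[NMBRecord, ...]

    @property
    def perspective(self) -> str:
        return self.outcomes[0].perspective

    def outcome(self, strategy: str) -> StrategyOutcome:
        for o in self.outcomes:
            if o.strategy == strategy:
                return o
        raise ValidationError(f"unknown strategy {strategy!r}")

    def inmb(self, strategy: str, wtp: float) -> float:
        for r in self.inmb_records:
            if r.strategy == strategy and r.wtp == wtp:
                return r.inmb
        raise ValidationError(f"no iNMB record for {strategy!r} at WTP {wtp}")

    def nmb_optimal(self, wtp_grid) -> dict[float, str]:
        """NMB-optimal strategy at each WTP (brute-force over outcomes)."""
        return frontier_nmb_oracle(self.outcomes, wtp_grid)

    def _status_label(self, strategy: str) -> str:
        status = self.frontier.status[strategy]
        if status == STRONGLY_DOMINATED:
            return "Dominated"
        if status == EXTENDEDLY_DOMINATED:
            return "Extendedly dominated"
        if strategy == self.reference:
            return "Reference"
        o, ref = self.outcome(strategy), self.outcome(self.reference)
        if o.expected_cost < ref.expected_cost and o.expected_qaly > ref.expected_qaly:
            return "Cost-saving, more effective"
        icer = self.frontier.frontier_icers.get(strategy)
        return f"{icer:.0f}" if icer is not None else "On frontier"

    def frame(self) -> pd.DataFrame:
        """Full-precision results table, cost-ordered."""
        rows = []
        for o in sorted(self.outcomes, key=lambda o: (o.expected_cost, o.strategy)):
            row = {
                "strategy": o.strategy,
                "expected_cost": o.expected_cost,
                "expected_qaly": o.expected_qaly,
                "status": self.frontier.status[o.strategy],
                "icer_or_status": self._status_label(o.strategy),
            }
            for w in self.wtps:
                row[f"inmb_{int(w/1000)}k"] = self.inmb(o.strategy, w)
            rows.append(row)
        return pd.DataFrame(rows)

    def report(self, qaly_decimals: int = 3) -> pd.DataFrame:
        """Display table: money to nearest dollar, QALYs to ``qaly_decimals``."""
        frame = self.frame()
        frame["expected_cost"] = frame["expected_cost"].round(0).astype("int64")
        frame["expected_qaly"] = frame["expected_qaly"].round(qaly_decimals)
        for w in self.wtps:
            col = f"inmb_{int(w/1000)}k"
            frame[col] = frame[col].round(0).astype("int64")
        return frame.drop(columns=["status"])

    def summary(self) -> str:
        """Readable base-case summary in the shape of a published table."""
        lines = [
            "Cost-effectiveness base case "
            f"({self.perspective} perspective, reference: {self.reference})",
            f"Efficient frontier: {', '.join(self.frontier.frontier)}",
            "",
            self.report().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_frontier(self, ax=None):
        from .plotting import plot_frontier

        return plot_frontier(self, ax=ax)


@dataclass(frozen=True)
class PSAResults:
    """PSA draws plus CEAC construction and display helpers."""

    raw: PSAResult
    wtps: tuple[float, ...]

    @property
    def strategies(self) -> tuple[str, ...]:
        return self.raw.strategies

    def ceac(self, wtp_grid=None) -> CEACCurve:
        if wtp_grid is None:
            top = max(self.wtps)
            wtp_grid = np.arange(0.0, top + 5000.0, 5000.0)
        return ceac(self.raw, wtp_grid)

    def summary(self) -> str:
        means = self.raw.mean_outcomes()
        frame = pd.DataFrame(
            {
                "strategy": [o.strategy for o in means],
                "mean_cost": [round(o.expected_cost) for o in means],
                "mean_qaly": [round(o.expected_qaly, 3) for o in means],
            }
        )
        head = (
            f"PSA: {self.raw.n_draws} draws, seed {self.raw.seed}, "
            f"{self.raw.perspective} perspective"
        )
        return head + "\n" + frame.to_string(index=False)

    def plot_ceac(self, wtp_grid=None, ax=None):
        from .plotting import plot_ceac

        return plot_ceac(self.ceac(wtp_grid), ax=ax)
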