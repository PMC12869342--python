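"""The complete input bundle for one analysis, with a flat parameter view.

``ModelInputs`` gathers everything one run needs: per-strategy transition
matrices, per-state utilities and annual costs, per-strategy drug costs,
the life table, cohort demographics and the run configuration. The flat
view (``to_flat`` / ``with_values``) names every scalar model parameter so
the PSA and one-way DSA can perturb any of them uniformly:

    tp.<strategy>.<from>.<to>   transition probability
    utility.<state>             QALY weight
    direct_medical.<state>      annual direct medical cost ($)
    direct_nonmedical.<state>   annual direct nonmedical cost ($)
    indirect.<state>            annual indirect (societal) cost ($)
    drug_cost.<strategy>        annual drug acquisition cost ($)

The life table and cohort demographics are structural inputs and are not
part of the flat parameter space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .economics import StateEconomics, StrategyOutcome, accrue_outcomes
from .errors import ValidationError
from .markov import CohortTrace, MortalityGrid, run_cohort
from .states import (
    ALIVE_STATES,
    CohortSpec,
    DiseaseTransitionMatrix,
    LifeTable,
    ModelConfig,
)

__all__ = ["ModelInputs"]


@dataclass
class ModelInputs:
    transitions: dict[str, DiseaseTransitionMatrix]
    utilities: dict[str, float]
    direct_medical: dict[str, float]
    direct_nonmedical: dict[str, float]
    indirect: dict[str, float] | None
    drug_costs: dict[str, float]
    life_table: LifeTable
    cohort: CohortSpec
    config: ModelConfig
    #: Enforce the severity ordering of utilities at validation time. Base
    #: inputs must satisfy it; PSA draws and DSA perturbations may invert it.
    ordered_utilities: bool = True

    def __post_init__(self) -> None:
        if set(self.transitions) != set(self.drug_costs):
            raise ValidationError(
                "transition matrices and drug costs cover different strategies"
            )
        for name, mat in self.transitions.items():
            if mat.strategy != name:
                raise ValidationError(
                    f"matrix registered under {name!r} is labelled {mat.strategy!r}"
                )
        # Construct one StateEconomics to run the shared validators.
        any_strategy = next(iter(self.transitions))
        self.econ_for(any_strategy)
        self._grid: MortalityGrid | None = None

    @property
    def strategies(self) -> tuple[str, ...]:
        return tuple(self.transitions)

    def econ_for(self, strategy: str) -> StateEconomics:
        if strategy not in self.drug_costs:
            raise ValidationError(f"unknown strategy {strategy!r}")
        return StateEconomics(
            strategy=strategy,
            utilities=self.utilities,
            direct_medical=self.direct_medical,
            direct_nonmedical=self.direct_nonmedical,
            indirect=self.indirect,
            drug_cost=self.drug_costs[strategy],
            ordered=self.ordered_utilities,
        )

    def mortality_grid(self) -> MortalityGrid:
        if self._grid is None:
            self._grid = MortalityGrid(self.cohort, self.life_table, self.config)
        return self._grid

    # -- flat parameter view -------------------------------------------------

    def to_flat(self) -> dict[str, float]:
        flat: dict[str, float] = {}
        for strat, mat in self.transitions.items():
            for i, fs in enumerate(ALIVE_STATES):
                for j, ts in enumerate(ALIVE_STATES):
                    flat[f"tp.{strat}.{fs}.{ts}"] = float(mat.probs[i, j])
        for s in ALIVE_STATES:
            flat[f"utility.{s}"] = float(self.utilities[s])
            flat[f"direct_medical.{s}"] = float(self.direct_medical[s])
            flat[f"direct_nonmedical.{s}"] = float(self.direct_nonmedical[s])
            if self.indirect is not None:
                flat[f"indirect.{s}"] = float(self.indirect[s])
        for strat, c in self.drug_costs.items():
            flat[f"drug_cost.{strat}"] = float(c)
        return flat

    def with_values(
        self,
        values: Mapping[str, float],
        renormalize_rows: bool = False,
    ) -> "ModelInputs":
        """A new input bundle with the given flat parameters overridden.

        ``renormalize_rows=True`` rescales any transition row touched by an
        override so it sums to 1 again (used by the one-way DSA; the PSA
        renormalizes at sampling time instead).
        """
        base = self.to_flat()
        unknown = sorted(set(values) - set(base))
        if unknown:
            raise ValidationError(f"unknown parameter {unknown[0]!r}")
        base.update({k: float(v) for k, v in values.items()})

        transitions: dict[str, DiseaseTransitionMatrix] = {}
        for strat in self.transitions:
            probs = np.array(
                [
                    [base[f"tp.{strat}.{fs}.{ts}"] for ts in ALIVE_STATES]
                    for fs in ALIVE_STATES
                ]
            )
            if renormalize_rows:
                touched = [
                    i
                    for i, fs in enumerate(ALIVE_STATES)
                    if any(f"tp.{strat}.{fs}.{ts}" in values for ts in ALIVE_STATES)
                ]
                for i in touched:
                    total = probs[i].sum()
                    if total <= 0:
                        raise ValidationError(
                            f"perturbed transition row {ALIVE_STATES[i]!r} for "
                            f"{strat!r} sums to 0"
                        )
                    probs[i] /= total
            transitions[strat] = DiseaseTransitionMatrix(strat, probs)

        utilities = {s: base[f"utility.{s}"] for s in ALIVE_STATES}
        dm = {s: base[f"direct_medical.{s}"] for s in ALIVE_STATES}
        dnm = {s: base[f"direct_nonmedical.{s}"] for s in ALIVE_STATES}
        ind = (
            {s: base[f"indirect.{s}"] for s in ALIVE_STATES}
            if self.indirect is not None
            else None
        )
        drug = {strat: base[f"drug_cost.{strat}"] for strat in self.drug_costs}
        new = ModelInputs(
            transitions=transitions,
            utilities=utilities,
            direct_medical=dm,
            direct_nonmedical=dnm,
            indirect=ind,
            drug_costs=drug,
            life_table=self.life_table,
            cohort=self.cohort,
            config=self.config,
            ordered_utilities=False,
        )
        new._grid = self._grid  # mortality is unchanged; reuse the grid
        return new

    # -- pipeline ------------------------------------------------------------

    def run_trace(self, strategy: str) -> CohortTrace:
        if strategy not in self.transitions:
            raise ValidationError(f"unknown strategy {strategy!r}")
        return run_cohort(
            self.transitions[strategy],
            self.cohort,
            self.life_table,
            self.config,
            grid=self.mortality_grid(),
        )

    def run_strategy(
        self, strategy: str, perspective: str | None = None
    ) -> StrategyOutcome:
        trace = self.run_trace(strategy)
        return accrue_outcomes(
            trace, self.econ_for(strategy), perspective, self.config
        )

    def run_all(
        self,
        perspective: str | None = None,
        strategies: Sequence[str] | None = None,
    ) -> list[StrategyOutcome]:
        names = list(strategies) if strategies is not None else list(self.strategies)
        return [self.run_strategy(s, perspective) for s in names]

    def replace_config(self, **kw) -> "ModelInputs":
        new = dataclasses.replace(self, config=self.config.replace(**kw))
        return new
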