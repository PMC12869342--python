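"""Parameter uncertainty: moment-matched distributions, PSA, CEAC, tornado.

Probabilistic sensitivity analysis is second-order Monte Carlo: every model
parameter carries a sampling distribution matched to its mean and standard
error — beta for probabilities, gamma for costs, lognormal for utilities
(capped at 1 after drawing) — and each draw re-runs the full deterministic
pipeline for every strategy. Transition-matrix rows are sampled entrywise
and renormalized to sum to 1 (an approximation to a Dirichlet row draw).

Deterministic (one-way) sensitivity analysis re-runs the pipeline at the
low and high end of each parameter's plausible range, holding everything
else at base case, and reports the swing in incremental net monetary
benefit as tornado bars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import StrategyOutcome, inmb
from .errors import InfeasibleMomentsError, ValidationError

__all__ = [
    "DistributionSpec",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_moments",
    "fixed_spec",
    "sample_parameter_set",
    "run_psa",
    "PSAResult",
    "ceac",
    "CEACCurve",
    "TornadoEntry",
    "one_way_sensitivity",
]

FAMILIES = ("beta", "gamma", "lognormal", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A parameter's sampling distribution, built by moment matching.

    ``params`` is family-specific: (alpha, beta) for beta, (shape, scale)
    for gamma, (mu, sigma) of the underlying normal for lognormal, and
    (value,) for fixed. ``upper`` optionally caps draws (used for utilities,
    which must not exceed 1); the cap is applied after sampling, so the
    analytic moments below describe the pre-cap distribution.
    """

    family: str
    params: tuple[float, ...]
    target_mean: float
    target_se: float
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")

    def analytic_mean(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            k, theta = self.params
            return k * theta
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2.0)
        return self.params[0]

    def analytic_var(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        if self.family == "gamma":
            k, theta = self.params
            return k * theta**2
        if self.family == "lognormal":
            mu, sigma = self.params
            return (math.exp(sigma**2) - 1.0) * math.exp(2.0 * mu + sigma**2)
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            out = rng.beta(*self.params, size=size)
        elif self.family == "gamma":
            out = rng.gamma(self.params[0], self.params[1], size=size)
        elif self.family == "lognormal":
            out = rng.lognormal(self.params[0], self.params[1], size=size)
        else:
            out = (
                float(self.params[0])
                if size is None
                else np.full(size, self.params[0])
            )
        if self.upper is not None:
            out = np.minimum(out, self.upper) if size is not None else min(out, self.upper)
        return out


def fixed_spec(value: float, upper: float | None = None) -> DistributionSpec:
    """A degenerate (point-mass) spec; used when SE is zero or unknown."""
    return DistributionSpec("fixed", (float(value),), float(value), 0.0, upper)


def beta_from_moments(mean: float, se: float) -> DistributionSpec:
    """Beta(alpha, beta) with the given mean and standard error.

    alpha = mean * k and beta = (1 - mean) * k with
    k = mean (1 - mean) / se^2 - 1. Requires se^2 < mean (1 - mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
    if se < 0:
        raise ValidationError("standard error must be nonnegative")
    if se == 0.0:
        return fixed_spec(mean)
    v = se**2
    if v >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta moments infeasible: se^2={v:.6g} >= mean(1-mean)={mean*(1-mean):.6g}"
        )
    k = mean * (1.0 - mean) / v - 1.0
    return DistributionSpec("beta", (mean * k, (1.0 - mean) * k), mean, se)


def gamma_from_moments(mean: float, se: float) -> DistributionSpec:
    """Gamma(shape, scale) with shape = mean^2/se^2, scale = se^2/mean."""
    if mean <= 0:
        raise ValidationError(f"gamma mean must be positive, got {mean}")
    if se < 0:
        raise ValidationError("standard error must be nonnegative")
    if se == 0.0:
        return fixed_spec(mean)
    v = se**2
    return DistributionSpec("gamma", (mean**2 / v, v / mean), mean, se)


def lognormal_from_moments(
    mean: float, se: float, upper: float | None = None
) -> DistributionSpec:
    """Lognormal with arithmetic mean/SE matched on the natural scale.

    sigma^2 = ln(1 + se^2/mean^2), mu = ln(mean) - sigma^2/2. ``upper``
    caps draws (set to 1 for utilities).
    """
    if mean <= 0:
        raise ValidationError(f"lognormal mean must be positive, got {mean}")
    if se < 0:
        raise ValidationError("standard error must be nonnegative")
    if se == 0.0:
        return fixed_spec(mean, upper)
    s2 = math.log(1.0 + se**2 / mean**2)
    mu = math.log(mean) - s2 / 2.0
    return DistributionSpec("lognormal", (mu, math.sqrt(s2)), mean, se, upper)


def sample_parameter_set(
    specs: Mapping[str, DistributionSpec],
    rng: np.random.Generator | int,
) -> dict[str, float]:
    """Draw one complete parameter realization.

    Parameters named ``tp.<strategy>.<from>.<to>`` are treated as
    transition-matrix entries: each (strategy, from) row is sampled
    entrywise and renormalized to sum to 1. Caps declared on a spec
    (utilities at 1) are applied per draw. Deterministic given the
    generator state / seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    values: dict[str, float] = {}
    for name in specs:  # insertion order => reproducible draw order
        values[name] = float(specs[name].sample(rng))
    rows: dict[tuple[str, str], list[str]] = {}
    for name in values:
        if name.startswith("tp."):
            parts = name.split(".")
            if len(parts) != 4:
                raise ValidationError(f"malformed transition parameter name {name!r}")
            rows.setdefault((parts[1], parts[2]), []).append(name)
    for (strategy, from_state), keys in rows.items():
        total = sum(values[k] for k in keys)
        if total <= 0:
            raise ValidationError(
                f"sampled transition row {from_state!r} for {strategy!r} sums to 0"
            )
        for k in keys:
            values[k] /= total
    return values


@dataclass(frozen=True)
class PSAResult:
    """Per-draw, per-strategy (cost, QALY) pairs from second-order Monte Carlo."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray  # (n_draws, n_strategies)
    n_draws: int
    seed: int
    perspective: str

    def __post_init__(self) -> None:
        if self.costs.shape != (self.n_draws, len(self.strategies)):
            raise ValidationError("PSA cost array shape mismatch")
        if self.qalys.shape != self.costs.shape:
            raise ValidationError("PSA qaly array shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), k),
                "strategy": list(self.strategies) * n,
                "cost": self.costs.ravel(),
                "qaly": self.qalys.ravel(),
            }
        )

    def mean_outcomes(self) -> list[StrategyOutcome]:
        return [
            StrategyOutcome(
                s,
                float(self.costs[:, j].mean()),
                float(self.qalys[:, j].mean()),
                self.perspective,
            )
            for j, s in enumerate(self.strategies)
        ]


def run_psa(
    inputs,
    specs: Mapping[str, DistributionSpec],
    n_draws: int = 1000,
    seed: int = 20240101,
    perspective: str | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over the full Markov + accrual pipeline.

    ``inputs`` is a :class:`fmcea.inputs.ModelInputs`. Every flattened model
    parameter must have a spec (``fixed`` allowed); a missing spec is an
    error naming the parameter. Each draw samples a complete realization,
    rebuilds the inputs, and runs every strategy.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be at least 1")
    if perspective is None:
        perspective = inputs.config.perspective
    base = inputs.to_flat()
    missing = sorted(set(base) - set(specs))
    if missing:
        raise ValidationError(f"no distribution spec for parameter {missing[0]!r}")
    rng = np.random.default_rng(int(seed))
    strategies = tuple(inputs.strategies)
    costs = np.empty((n_draws, len(strategies)))
    qalys = np.empty_like(costs)
    for d in range(n_draws):
        values = sample_parameter_set(specs, rng)
        drawn = inputs.with_values(values)
        for j, outcome in enumerate(drawn.run_all(perspective)):
            costs[d, j] = outcome.expected_cost
            qalys[d, j] = outcome.expected_qaly
    return PSAResult(strategies, costs, qalys, n_draws, int(seed), perspective)


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is NMB-optimal, per WTP threshold."""

    strategies: tuple[str, ...]
    wtp: np.ndarray  # (W,)
    probabilities: np.ndarray  # (W, n_strategies); rows sum to 1

    def __post_init__(self) -> None:
        if np.any(np.abs(self.probabilities.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("CEAC probabilities must sum to 1 at each WTP")

    def probability(self, strategy: str) -> np.ndarray:
        return self.probabilities[:, self.strategies.index(strategy)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (strategy, wtp, probability) frame, plot-ready."""
        w = len(self.wtp)
        return pd.DataFrame(
            {
                "strategy": np.repeat(self.strategies, w),
                "wtp": np.tile(self.wtp, len(self.strategies)),
                "probability": self.probabilities.T.ravel(),
            }
        )


def ceac(psa: PSAResult, wtp_grid: Iterable[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each threshold the probability assigned to a strategy is the fraction
    of draws in which it attains the maximum net monetary benefit; exact
    ties within a draw split the draw's mass equally.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("wtp grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValidationError("wtp grid must be ascending")
    probs = np.empty((grid.size, len(psa.strategies)))
    for i, w in enumerate(grid):
        nmb = w * psa.qalys - psa.costs  # (n_draws, K)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(psa.strategies, grid, probs)


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a tornado diagram: iNMB swing over a parameter's range."""

    parameter: str
    low_value: float
    high_value: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


_DOMAIN_BOUNDS = {
    "tp": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "direct_medical": (0.0, math.inf),
    "direct_nonmedical": (0.0, math.inf),
    "indirect": (0.0, math.inf),
    "drug_cost": (0.0, math.inf),
}


def _check_range(name: str, base: float, low: float, high: float) -> None:
    prefix = name.split(".")[0]
    lo_bound, hi_bound = _DOMAIN_BOUNDS.get(prefix, (-math.inf, math.inf))
    if not low <= base <= high:
        raise ValidationError(
            f"range for {name!r} must satisfy low <= base <= high "
            f"({low} <= {base} <= {high})"
        )
    if low < lo_bound or high > hi_bound:
        raise ValidationError(
            f"range [{low}, {high}] for {name!r} leaves its domain "
            f"[{lo_bound}, {hi_bound}]"
        )


def default_ranges(
    base: Mapping[str, float], fraction: float = 0.2
) -> dict[str, tuple[float, float]]:
    """Plausible ranges of +/- `fraction` around base, clipped to domains."""
    out = {}
    for name, v in base.items():
        prefix = name.split(".")[0]
        lo_b, hi_b = _DOMAIN_BOUNDS.get(prefix, (-math.inf, math.inf))
        out[name] = (
            max(lo_b, v * (1.0 - fraction)),
            min(hi_b, v * (1.0 + fraction)),
        )
    return out


def one_way_sensitivity(
    inputs,
    param_ranges: Mapping[str, tuple[float, float]],
    target_pair: tuple[str, str],
    wtp: float,
    perspective: str | None = None,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis (tornado).

    For each parameter, re-runs the deterministic pipeline with that
    parameter at the low and at the high end of its plausible range (all
    others at base case) and records the iNMB of ``target_pair`` =
    (candidate, reference) at the given WTP. Entries are sorted by
    descending bar width. Transition-row parameters are renormalized within
    their row after the perturbation so rows remain stochastic.
    """
    candidate, reference = target_pair
    if perspective is None:
        perspective = inputs.config.perspective
    base = inputs.to_flat()
    unknown = sorted(set(param_ranges) - set(base))
    if unknown:
        raise ValidationError(f"unknown parameter {unknown[0]!r} in ranges")

    def _inmb_at(name: str, value: float) -> float:
        perturbed = inputs.with_values({name: value}, renormalize_rows=True)
        out_c = perturbed.run_strategy(candidate, perspective)
        out_r = perturbed.run_strategy(reference, perspective)
        return inmb(out_c, out_r, wtp).inmb

    entries = []
    for name, (low, high) in param_ranges.items():
        _check_range(name, base[name], low, high)
        entries.append(
            TornadoEntry(name, low, high, _inmb_at(name, low), _inmb_at(name, high))
        )
    entries.sort(key=lambda e: (-e.bar_width, e.parameter))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low_value for e in entries],
            "high": [e.high_value for e in entries],
            "inmb_low": [e.inmb_at_low for e in entries],
            "inmb_high": [e.inmb_at_high for e in entries],
            "width": [e.bar_width for e in entries],
        }
    )
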