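# Methods

## Model structure

The disease process is a Markov cohort model with three alive severity
states — mild (pain 0–3), moderate (4–6), severe (7–10) on the 11-point
numeric rating scale — plus absorbing death. Cycles are annual. Each
treatment strategy is a 3×3 row-stochastic matrix of annual transition
probabilities among the alive states, *conditional on surviving the
cycle*; the full 4×4 cycle matrix scales that block by the survival
probability and routes the complement into death. Mortality is therefore
state-independent: treatment affects quality of life (and costs) through
the severity distribution, not survival. This mirrors the usual structure
of fibromyalgia decision models, where the condition is burdensome but
not itself fatal.

The horizon is lifetime: cycles continue until the alive fraction of the
cohort falls to `extinction_epsilon` (default 1e-7) or every age stratum
passes `max_age` (default 100, where death is forced). A hard internal cap
of 200 cycles turns a non-terminating configuration into an explicit
error rather than a hang. `max_cycles` can truncate the horizon for
diagnostics and tests.

## Cohort heterogeneity

The target population is adults with moderate to severe fibromyalgia:
94.4% female, age distributed normal with mean 48.4 and SD 10.4 years.
The entering age distribution is discretized into integer-age strata on
[18, 90] (each stratum's weight is the normal probability mass of its
1-year bin, renormalized — about 73 strata). Every stratum runs the same
severity dynamics but its own age path: a stratum aged *a* at entry faces
the life-table hazard at age *a + t* in cycle *t*. Sex enters only
through the mortality mix, `q(a) = 0.944 q_f(a) + 0.056 q_m(a)`. Strata
are aggregated by weight; because the model is linear in the occupancy
vector this is exact, not an approximation. Entry is split between the
moderate and severe states; the split is configurable and defaults to
(0.5, 0.5), an unbiased choice where no published split exists.

## Accrual, half-cycle correction, discounting

State membership changes mid-cycle in reality, so person-time credited to
cycle *t* uses the trapezoidal (standard life-table) correction: the
average of start- and end-of-cycle alive occupancy. The same corrected
weights feed both QALYs (weighted by state utilities) and costs (weighted
by per-state annual cost), so the correction applies identically to both
outcome streams. Discounting is discrete annual, `(1+r)^(-t)` applied to
cycle *t*'s corrected accrual, with `r = 0.03` by default.

Per-state annual costs are direct medical + direct nonmedical + the
strategy's drug acquisition cost; the societal perspective adds indirect
costs (productivity losses, work absences, caregiving). Drug cost
accrues for every alive person-year — lifetime therapy with no
discontinuation, matching the structural assumption of no adverse-event
or discontinuation states. Indirect costs arrive in input files as
3-month estimates (the convention of their source literature) and are
annualized ×4 at ingestion.

## Comparative economics

`build_frontier` sorts strategies by ascending cost, removes strong
dominance (another strategy costs no more and yields no fewer QALYs, with
one strict inequality), then iteratively removes extended dominance:
among cost-ordered survivors, any strategy whose adjacent ICER is not
strictly below the next adjacent ICER is excluded, until the ICER
sequence strictly increases. Tie rules are deterministic: equal cost and
equal QALYs — both retained, ordered lexicographically; equal cost,
different QALYs — the lower-QALY strategy is strongly dominated.
`frontier_nmb_oracle` is an independent brute-force verifier (argmax of
`W·QALY − cost` over a dense WTP grid) used by the tests: every grid
optimum, plus the cheapest strategy, must lie on the frontier.

ICER and iNMB are computed at full precision; rounding to the nearest
dollar (and QALYs to 2–3 decimals) happens only in report rendering.
Note that in published tables the iNMB cells of *dominated* strategies
are not always exactly consistent with the printed cost/QALY columns
(they were evidently computed from unrounded internals); this package's
tests assert only the self-consistent cells.

## Probabilistic sensitivity analysis

Every flat model parameter carries a sampling distribution matched to its
mean and standard error:

- **beta** for transition probabilities: `k = m(1−m)/se² − 1`,
  `α = mk`, `β = (1−m)k` (requires `se² < m(1−m)`);
- **gamma** for costs: `shape = m²/se²`, `scale = se²/m`;
- **lognormal** for utilities: `σ² = ln(1 + se²/m²)`, `μ = ln m − σ²/2`,
  chosen for its behaviour near zero (severe disease, old age); draws are
  capped at 1 after sampling since utilities are bounded above;
- **fixed** (point mass) whenever `se = 0`.

Transition rows are multinomial but the assigned family is beta, so each
row is sampled entrywise and renormalized to sum to 1 — a documented
approximation to a Dirichlet row draw. Where a source provides only a
mean, the default standard error is 20% of the mean.

A PSA run draws `n` complete parameter realizations (default 1000) from a
single seeded `numpy` generator and pushes each through the full Markov +
accrual pipeline for every strategy. The life table and cohort
demographics are treated as structural and held fixed. CEAC probabilities
at each WTP are the fraction of draws in which a strategy attains the
maximum net monetary benefit; exact ties split the draw's mass equally,
so the curves sum to 1 at every threshold by construction. The PSA seed
is a recorded input (default 20240101).

## One-way sensitivity analysis

Each parameter is set to the low and high end of its plausible range with
everything else at base case, and the iNMB of a chosen (candidate,
reference) pair at a chosen WTP is recorded; bars are sorted by swing
width. Ranges default to ±20% of base, clipped to domain bounds
(probabilities and utilities to [0, 1], costs to [0, ∞)), and are
overridable per parameter via the ranges file; a range leaving the domain
is an error, not a silent clip. Perturbed transition entries are
renormalized within their row so rows remain stochastic.

## Synthetic inputs

`fmcea.synthetic` emulates the statistical structure of the study's
(non-public) input tables rather than their values:

- Ten strategies, each defined by one scalar *effectiveness gradient*
  `g ∈ [0, 1]` that moves transition-row mass toward the next-better
  state (persistence mass for the moderate/severe rows; deterioration
  mass pulled back for the mild row), then clips and renormalizes. The
  default gradients reproduce the published ordinal effectiveness ranking
  (duloxetine 120 mg best, pregabalin 450 mg next, amitriptyline
  mid-pack, milnacipran weakest, no treatment = natural history, g = 0).
- Severity-ordered utilities (0.85 / 0.72 / 0.55) and annual state costs
  (direct medical 4 000 / 7 000 / 11 000; direct nonmedical 500 / 1 000 /
  2 000), with indirect costs (6 000 / 15 000 / 30 000 $/yr) large enough
  that societal totals far exceed payer totals, as in working-age chronic
  pain populations.
- Annual drug costs spanning generic amitriptyline ($60) to branded
  milnacipran ($6 200).
- A Gompertz life table `q(a) = min(1, A e^{0.085 a})` with female
  baseline `A = 2.2e-5` and male mortality 1.6× higher, terminal age
  closed at `q = 1`.

Generation is fully deterministic from the scenario fields; the scenario
seed is recorded and reused as the default PSA seed rather than used to
jitter values, which could silently break the ordinal invariants the
generator is required to satisfy. What the generator does *not* emulate:
the actual magnitudes of the published lifetime totals, the
network-meta-analysis posterior correlations between strategies, and any
age- or time-dependence of treatment effect. Tests passing on synthetic
inputs therefore validate the machinery (conservation, dominance logic,
estimator algebra, reproducibility), not the study's clinical inputs.

The published per-strategy lifetime (cost, QALY) tables for both
perspectives are stored verbatim as fixtures (`table_fixture`); they feed
the comparative layer directly, bypassing the Markov engine, and are
never recomputed.

## Numerical choices

- Transition-row sums are validated to 1e-9; cycle-matrix rows to 1e-12;
  occupancy conservation and CEAC normalization asserted at 1e-9.
- ICER for a pair with equal QALYs is an explicit `UndefinedICERError`;
  callers classify such pairs via dominance instead.
- Extended-dominance removal uses `ICER_i >= ICER_{i+1}` (collinear
  middle points are removed), which guarantees strictly increasing
  frontier ICERs.
- Ages beyond the life table's terminal row clamp to it; ages below its
  minimum are an error naming the age.
- The deterministic base case for the default scenario runs ~83 cycles ×
  73 strata per strategy; a 1000-draw PSA of all ten strategies completes
  in well under a minute, which is the problem size used by the test
  suite and the acceptance script.

## Known limitations

- No microsimulation: patient-level heterogeneity beyond age/sex strata
  (e.g., heterogeneous treatment response) is out of scope.
- No adverse-event, discontinuation, dose-titration or treatment-sequence
  states; treatment effect is constant for life.
- PSA samples parameters independently (apart from row renormalization);
  no correlation structure, and no value-of-information analysis.
- The synthetic inputs are structural stand-ins; absolute lifetime totals
  computed from them are not comparable to published totals.
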