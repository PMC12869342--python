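# fmcea

Cost-effectiveness analysis of pharmacologic treatments for moderate to
severe fibromyalgia, built as a reusable, tested modelling package. It is
aimed at health-economics and outcomes researchers who want a transparent,
scriptable alternative to spreadsheet or platform-based Markov models:
every stage — the cohort engine, the comparative economics, and the
sensitivity analyses — is an importable, unit-tested function.

## The model

A **Markov cohort state-transition model** with four health states — mild
(pain 0–3), moderate (4–6), severe (7–10) on an 11-point pain scale, and
death (absorbing) — run in annual cycles over a lifetime horizon. Ten
strategies are compared: amitriptyline, pregabalin 150/300/450/600 mg,
duloxetine 60/120 mg, milnacipran 100/200 mg, and no treatment. Each
strategy has its own 3×3 annual transition matrix among the alive states,
conditional on survival; background mortality comes from an age- and
sex-specific life table and applies equally to all alive states.

For strategy *s* with per-cycle effective (half-cycle-corrected) state
occupancy *ŷ<sub>t</sub>*, utilities *u*, per-state annual costs *c*, and
discount rate *r* = 3%/yr:

- QALYs(s) = Σ<sub>t</sub> (1+r)<sup>−t</sup> ŷ<sub>t</sub>·u
- Cost(s) = Σ<sub>t</sub> (1+r)<sup>−t</sup> ŷ<sub>t</sub>·c, with
  *c* = direct medical + direct nonmedical + drug acquisition
  (+ indirect costs under the societal perspective)
- ICER = ΔCost/ΔQALY between adjacent nondominated strategies
- iNMB(W) = W·ΔQALY − ΔCost at willingness-to-pay W ∈ {$50k, $100k, $150k}/QALY

Strategies are classified by **strong dominance** (another option is at
least as cheap and at least as effective) and **extended dominance**
(adjacent ICERs must increase strictly along the cost-ordered survivors);
the survivors form the efficiency frontier. Uncertainty is handled by
one-way deterministic sensitivity analysis (tornado) and probabilistic
sensitivity analysis (1000 second-order Monte Carlo draws; beta
distributions for transition probabilities, gamma for costs, lognormal for
utilities, all moment-matched), summarized as cost-effectiveness
acceptability curves (CEAC).

The original study's input tables are not public, so `fmcea.synthetic`
generates complete, internally consistent stand-ins with the same
structure, and ships the published per-strategy lifetime (cost, QALY)
tables verbatim so the comparative layer can be checked against the
printed results exactly.

## Worked example

```python
from fmcea import evaluate_outcomes, table_fixture

results = evaluate_outcomes(
    table_fixture("payer"),
    wtps=(50_000, 100_000, 150_000),
    reference="amitriptyline",
)
print(results.summary())
```

```
Cost-effectiveness base case (payer perspective, reference: amitriptyline)
Efficient frontier: amitriptyline, duloxetine 120 mg

          strategy  expected_cost  expected_qaly icer_or_status  inmb_50k  inmb_100k  inmb_150k
     amitriptyline         115145          9.994      Reference         0          0          0
 duloxetine 120 mg         115770         10.401           1536     19725      40075      60425
 pregabalin 450 mg         117434         10.233      Dominated      9661      21611      33561
 ...
milnacipran 200 mg         242864          9.532      Dominated   -150819    -173919    -197019
```

Reading this: duloxetine 120 mg buys 0.407 extra QALYs over amitriptyline
for $625 extra lifetime cost — an ICER of $1536 per QALY, far below every
conventional threshold, and an incremental net monetary benefit of
$40 075 at $100 000/QALY. Every other strategy costs more and delivers
fewer QALYs than one of those two, so all are strongly dominated.

The full simulation pipeline works the same way from synthetic inputs:

```python
from fmcea import MarkovCEA
from fmcea.synthetic import generate_parameter_set

inputs, specs = generate_parameter_set()   # 10 strategies, full input set
model = MarkovCEA(inputs, specs)
base = model.fit()                         # deterministic base case
psa = model.psa(n_draws=1000, seed=20240101)
curve = psa.ceac()                         # acceptability curves
```

Or from the shell:

```bash
fmcea synth --out inputs/
fmcea run   --inputs inputs/ --out base/
fmcea psa   --inputs inputs/ --out psa/ --n 1000 --seed 20240101
fmcea owsa  --inputs inputs/ --ranges ranges.csv \
            --candidate "duloxetine 120 mg" --reference amitriptyline \
            --out owsa/
fmcea run   --fixture payer --reference amitriptyline --out published/
```

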