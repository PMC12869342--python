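"""Distribution moment matching, PSA, CEAC, and one-way sensitivity."""

import math

import numpy as np
import pytest
from scipy import stats

from fmcea.cea import MarkovCEA
from fmcea.errors import InfeasibleMomentsError, ValidationError
from fmcea.synthetic import SyntheticScenario, generate_parameter_set
from fmcea.uncertainty import (
    CEACCurve,
    PSAResult,
    beta_from_moments,
    ceac,
    fixed_spec,
    gamma_from_moments,
    lognormal_from_moments,
    one_way_sensitivity,
    run_psa,
    sample_parameter_set,
)

# ---------------------------------------------------------------------------
# moment matching


class TestMomentMatching:
    def test_beta_hand_example(self):
        spec = beta_from_moments(0.5, math.sqrt(0.025))
        assert spec.params == pytest.approx((4.5, 4.5))

    def test_beta_zero_se_degenerates_to_fixed(self):
        assert beta_from_moments(0.3, 0.0).family == "fixed"

    def test_beta_infeasible_moments(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.99, 0.2)

    def test_gamma_hand_example(self):
        spec = gamma_from_moments(100.0, 10.0)
        assert spec.params == pytest.approx((100.0, 1.0))

    def test_gamma_mean_equals_se_is_exponential(self):
        assert gamma_from_moments(5.0, 5.0).params[0] == pytest.approx(1.0)

    def test_gamma_rejects_nonpositive_mean(self):
        with pytest.raises(ValidationError):
            gamma_from_moments(0.0, 1.0)

    def test_lognormal_zero_se_is_fixed_point(self):
        spec = lognormal_from_moments(1.0, 0.0)
        assert spec.family == "fixed" and spec.params == (1.0,)

    def test_lognormal_hand_example(self):
        spec = lognormal_from_moments(0.7, 0.1)
        s2 = math.log(1 + 0.01 / 0.49)
        assert spec.params[1] ** 2 == pytest.approx(s2, rel=1e-9)
        assert spec.params[0] == pytest.approx(math.log(0.7) - s2 / 2, rel=1e-9)

    @pytest.mark.parametrize(
        "spec",
        [
            beta_from_moments(0.3, 0.08),
            gamma_from_moments(7000.0, 1400.0),
            lognormal_from_moments(0.72, 0.144),
        ],
        ids=["beta", "gamma", "lognormal"],
    )
    def test_analytic_moments_match_targets_and_scipy(self, spec):
        """Closed-form moments hit the targets; scipy is the cross-check."""
        assert spec.analytic_mean() == pytest.approx(spec.target_mean, rel=1e-12)
        assert spec.analytic_var() == pytest.approx(spec.target_se**2, rel=1e-12)
        if spec.family == "beta":
            dist = stats.beta(*spec.params)
        elif spec.family == "gamma":
            dist = stats.gamma(spec.params[0], scale=spec.params[1])
        else:
            dist = stats.lognorm(spec.params[1], scale=math.exp(spec.params[0]))
        assert dist.mean() == pytest.approx(spec.target_mean, rel=1e-12)
        assert dist.var() == pytest.approx(spec.target_se**2, rel=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [
            beta_from_moments(0.3, 0.08),
            gamma_from_moments(7000.0, 1400.0),
            lognormal_from_moments(0.72, 0.144),
        ],
        ids=["beta", "gamma", "lognormal"],
    )
    def test_empirical_mean_within_three_mc_standard_errors(self, spec):
        rng = np.random.default_rng(123)
        n = 100_000
        draws = spec.sample(rng, size=n)
        mc_se = spec.target_se / math.sqrt(n)
        assert abs(float(np.mean(draws)) - spec.target_mean) < 3 * mc_se


# ---------------------------------------------------------------------------
# sampling


class TestSampleParameterSet:
    def test_all_fixed_returns_base_case(self, small_scenario):
        inputs, _ = generate_parameter_set(small_scenario)
        base = inputs.to_flat()
        specs = {k: fixed_spec(v) for k, v in base.items()}
        assert sample_parameter_set(specs, 0) == pytest.approx(base)

    def test_transition_row_renormalized(self):
        specs = {
            "tp.s.moderate.mild": fixed_spec(0.2),
            "tp.s.moderate.moderate": fixed_spec(0.5),
            "tp.s.moderate.severe": fixed_spec(0.5),
        }
        values = sample_parameter_set(specs, 0)
        assert values["tp.s.moderate.mild"] == pytest.approx(1 / 6)
        assert values["tp.s.moderate.moderate"] == pytest.approx(5 / 12)
        assert values["tp.s.moderate.severe"] == pytest.approx(5 / 12)

    def test_same_seed_identical_realization(self, small_scenario):
        inputs, specs = generate_parameter_set(small_scenario)
        assert sample_parameter_set(specs, 42) == sample_parameter_set(specs, 42)

    def test_utility_draws_capped_at_one(self):
        spec = lognormal_from_moments(0.98, 0.3, upper=1.0)
        rng = np.random.default_rng(0)
        assert float(np.max(spec.sample(rng, size=5000))) <= 1.0


# ---------------------------------------------------------------------------
# PSA


class TestPSA:
    def test_degenerate_psa_equals_base_case(self, small_scenario):
        inputs, _ = generate_parameter_set(small_scenario)
        specs = {k: fixed_spec(v) for k, v in inputs.to_flat().items()}
        psa = run_psa(inputs, specs, n_draws=3, seed=1)
        base = {o.strategy: o for o in inputs.run_all()}
        for j, s in enumerate(psa.strategies):
            assert np.allclose(psa.costs[:, j], base[s].expected_cost, atol=1e-9)
            assert np.allclose(psa.qalys[:, j], base[s].expected_qaly, atol=1e-9)

    def test_two_draws_match_manual_composition(self, small_scenario):
        inputs, specs = generate_parameter_set(small_scenario)
        psa = run_psa(inputs, specs, n_draws=2, seed=9)
        rng = np.random.default_rng(9)
        for d in range(2):
            values = sample_parameter_set(specs, rng)
            outs = inputs.with_values(values).run_all()
            assert psa.costs[d] == pytest.approx(
                [o.expected_cost for o in outs], rel=1e-12
            )
            assert psa.qalys[d] == pytest.approx(
                [o.expected_qaly for o in outs], rel=1e-12
            )

    def test_missing_spec_names_parameter(self, small_scenario):
        inputs, specs = generate_parameter_set(small_scenario)
        specs = dict(specs)
        specs.pop("utility.moderate")
        with pytest.raises(ValidationError, match="utility.moderate"):
            run_psa(inputs, specs, n_draws=1, seed=0)

    def test_psa_mean_tracks_base_case_for_linear_parameters(self, small_scenario):
        # With transitions held fixed, outcomes are linear in the sampled
        # cost/utility parameters, so the PSA mean should sit within 3 MC
        # standard errors of the base case.
        inputs, specs = generate_parameter_set(small_scenario)
        base_flat = inputs.to_flat()
        lin_specs = {
            k: (v if not k.startswith("tp.") else fixed_spec(base_flat[k]))
            for k, v in specs.items()
        }
        n = 200
        psa = run_psa(inputs, lin_specs, n_draws=n, seed=5)
        base = {o.strategy: o for o in inputs.run_all()}
        for j, s in enumerate(psa.strategies):
            draws = psa.costs[:, j]
            mc_se = draws.std(ddof=1) / math.sqrt(n)
            assert abs(draws.mean() - base[s].expected_cost) < 3 * mc_se


# ---------------------------------------------------------------------------
# CEAC


def manual_psa(costs, qalys, strategies=("A", "B")):
    costs = np.asarray(costs, float)
    qalys = np.asarray(qalys, float)
    return PSAResult(tuple(strategies), costs, qalys, costs.shape[0], 0, "payer")


class TestCEAC:
    def test_single_strategy_probability_one(self):
        psa = manual_psa([[1.0]] * 4, [[1.0]] * 4, strategies=("only",))
        curve = ceac(psa, [0, 50_000, 100_000])
        assert np.all(curve.probabilities == 1.0)

    def test_counting_rule(self):
        # A wins 3 of 4 draws at wtp 0 (cheaper); B wins once.
        costs = [[1, 2], [1, 2], [1, 2], [2, 1]]
        qalys = [[1, 1], [1, 1], [1, 1], [1, 1]]
        curve = ceac(manual_psa(costs, qalys), [0.0])
        assert curve.probabilities[0] == pytest.approx([0.75, 0.25])

    def test_exact_ties_split_mass(self):
        costs = [[1, 1]] * 4
        qalys = [[1, 1]] * 4
        curve = ceac(manual_psa(costs, qalys), [0.0, 1e5])
        assert np.all(curve.probabilities == 0.5)

    def test_dominated_in_every_draw_has_zero_probability(self):
        rng = np.random.default_rng(3)
        a_cost = rng.uniform(100, 200, 50)
        a_qaly = rng.uniform(5, 6, 50)
        costs = np.column_stack([a_cost, a_cost + 10])
        qalys = np.column_stack([a_qaly, a_qaly - 0.5])
        curve = ceac(manual_psa(costs, qalys), np.arange(0, 2e5, 1e4))
        assert np.all(curve.probability("B") == 0.0)

    def test_normalization_invariant(self, small_scenario):
        inputs, specs = generate_parameter_set(small_scenario)
        psa = run_psa(inputs, specs, n_draws=30, seed=2)
        curve = ceac(psa, np.arange(0, 155_000, 5000.0))
        assert np.allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            ceac(manual_psa([[1.0]], [[1.0]], strategies=("x",)), [])

    def test_scenario_recovery_dominant_strategy(self):
        """A strategy with the best transitions and the lowest drug cost,
        under tightly concentrated distributions, should win the CEAC
        nearly surely at every threshold."""
        scenario = SyntheticScenario(
            strategies=("winner", "also-ran", "no treatment"),
            gradients={"winner": 0.45, "also-ran": 0.1, "no treatment": 0.0},
            drug_costs={"winner": 10.0, "also-ran": 900.0, "no treatment": 0.0},
            se_fraction=0.02,
            cohort=type(generate_parameter_set()[0].cohort)(sd_age=0.0),
        )
        inputs, specs = generate_parameter_set(scenario)
        psa = run_psa(inputs, specs, n_draws=150, seed=77)
        curve = ceac(psa, np.arange(0, 160_000, 10_000.0))
        assert np.all(curve.probability("winner") > 0.95)


# ---------------------------------------------------------------------------
# one-way sensitivity


class TestOneWay:
    def test_zero_width_range_gives_zero_bar(self, small_scenario):
        inputs, _ = generate_parameter_set(small_scenario)
        base = inputs.to_flat()["utility.moderate"]
        entries = one_way_sensitivity(
            inputs,
            {"utility.moderate": (base, base)},
            ("duloxetine 120 mg", "amitriptyline"),
            100_000.0,
        )
        assert entries[0].bar_width == 0.0

    def test_drug_cost_swing_matches_person_year_linearity(self, small_scenario):
        # Varying the candidate's drug cost by +/- delta moves iNMB by
        # -/+ delta * (discounted alive person-years) exactly.
        inputs, _ = generate_parameter_set(small_scenario)
        name = "drug_cost.duloxetine 120 mg"
        base = inputs.to_flat()[name]
        delta = 200.0
        entries = one_way_sensitivity(
            inputs,
            {name: (base - delta, base + delta)},
            ("duloxetine 120 mg", "amitriptyline"),
            100_000.0,
        )
        trace = inputs.run_trace("duloxetine 120 mg")
        py = trace.person_years(inputs.config.discount_rate)
        e = entries[0]
        assert e.inmb_at_low - e.inmb_at_high == pytest.approx(
            2 * delta * py, rel=1e-9
        )

    def test_unreferenced_parameter_has_zero_width(self, small_scenario):
        inputs, _ = generate_parameter_set(small_scenario)
        name = "drug_cost.no treatment"
        base = inputs.to_flat()[name]
        entries = one_way_sensitivity(
            inputs,
            {name: (base, base + 500.0)},
            ("duloxetine 120 mg", "amitriptyline"),
            100_000.0,
        )
        assert entries[0].bar_width == pytest.approx(0.0, abs=1e-9)

    def test_domain_violation_rejected(self, small_scenario):
        inputs, _ = generate_parameter_set(small_scenario)
        base = inputs.to_flat()["utility.moderate"]
        with pytest.raises(ValidationError, match="domain"):
            one_way_sensitivity(
                inputs,
                {"utility.moderate": (base, 1.4)},
                ("duloxetine 120 mg", "amitriptyline"),
                100_000.0,
            )

    def test_entries_sorted_by_descending_width(self, small_scenario):
        from fmcea.uncertainty import default_ranges

        inputs, _ = generate_parameter_set(small_scenario)
        ranges = default_ranges(inputs.to_flat())
        subset = {
            k: v
            for k, v in ranges.items()
            if k.startswith(("utility.", "drug_cost."))
        }
        entries = one_way_sensitivity(
            inputs, subset, ("duloxetine 120 mg", "amitriptyline"), 100_000.0
        )
        widths = [e.bar_width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_moderate_utility_leads_when_arms_differ_in_moderate_occupancy(self):
        # The candidate converts severe occupancy into moderate occupancy
        # against a stay-put reference, so between-arm QALY differences live
        # in the moderate (and severe) states; with proportional ranges the
        # moderate-state utility must produce the widest tornado bar.
        from fmcea.inputs import ModelInputs
        from fmcea.states import CohortSpec, DiseaseTransitionMatrix, ModelConfig
        from fmcea.synthetic import generate_life_table

        candidate = DiseaseTransitionMatrix(
            "candidate", [[1, 0, 0], [0, 1, 0], [0, 1, 0]]
        )
        reference = DiseaseTransitionMatrix("no treatment", np.eye(3))
        inputs = ModelInputs(
            transitions={"candidate": candidate, "no treatment": reference},
            utilities={"mild": 0.85, "moderate": 0.72, "severe": 0.55},
            direct_medical={"mild": 4000.0, "moderate": 7000.0, "severe": 11000.0},
            direct_nonmedical={"mild": 500.0, "moderate": 1000.0, "severe": 2000.0},
            indirect=None,
            drug_costs={"candidate": 100.0, "no treatment": 0.0},
            life_table=generate_life_table(2.2e-5, 0.085),
            cohort=CohortSpec(sd_age=0.0),
            config=ModelConfig(),
        )
        flat = inputs.to_flat()
        ranges = {
            k: (flat[k] * 0.8, min(1.0, flat[k] * 1.2))
            for k in ("utility.mild", "utility.moderate", "utility.severe")
        }
        entries = one_way_sensitivity(
            inputs, ranges, ("candidate", "no treatment"), 100_000.0
        )
        assert entries[0].parameter == "utility.moderate"
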