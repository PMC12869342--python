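import hypothesis
import numpy as np
import pandas as pd
import pytest

from fmcea.states import CohortSpec, DiseaseTransitionMatrix, LifeTable, ModelConfig

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, deadline=None, max_examples=60)
)
hypothesis.settings.load_profile("ci")


def make_life_table(qx_female, qx_male=None, min_age=18, max_age=100, validate=True):
    """Constant-rate life table helper; callables receive the age array."""
    ages = np.arange(min_age, max_age + 1)
    if qx_male is None:
        qx_male = qx_female
    rows = []
    for sex, q in (("female", qx_female), ("male", qx_male)):
        vals = q(ages) if callable(q) else np.full(len(ages), float(q))
        if validate:
            vals = vals.copy()
            vals[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": vals}))
    return LifeTable(pd.concat(rows, ignore_index=True), validate=validate)


@pytest.fixture
def zero_mortality_table():
    return make_life_table(0.0, validate=False)


@pytest.fixture
def half_mortality_table():
    """Constant qx = 0.5 for both sexes (terminal row still closes at 1)."""
    return make_life_table(0.5)


@pytest.fixture
def single_stratum_cohort():
    """One 50-year-old, all-female, all entering in the moderate state."""
    return CohortSpec(
        mean_age=50.0,
        sd_age=0.0,
        prop_female=1.0,
        initial_state_split=(1.0, 0.0),
    )


@pytest.fixture
def identity_matrix():
    return DiseaseTransitionMatrix("stay", np.eye(3))


@pytest.fixture
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def default_synthetic():
    from fmcea.synthetic import generate_parameter_set

    return generate_parameter_set()


@pytest.fixture(scope="session")
def small_scenario():
    """Three-strategy scenario for fast PSA/DSA tests."""
    from fmcea.synthetic import SyntheticScenario

    return SyntheticScenario(
        strategies=("amitriptyline", "duloxetine 120 mg", "no treatment"),
        cohort=CohortSpec(sd_age=0.0),
    )
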