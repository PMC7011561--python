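import numpy as np
import pandas as pd
import pytest

from teh import SimScenario, TrialData, generate_trial, scenario_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def toy_trial():
    """Deterministic 10-subject trial for partition bookkeeping checks."""
    return TrialData(
        subject_id=np.array([f"p{i}" for i in range(10)]),
        X=pd.DataFrame({"age": np.arange(10.0), "sex": list("MFMFMFMFMF")}),
        T=np.array([0, 1] * 5),
        Y=np.array([0, 0, 1, 1, 0, 1, 0, 1, 0, 1]),
    )


@pytest.fixture
def null_trial():
    """Medium null trial (no treatment effect, no heterogeneity)."""
    data, _ = generate_trial(scenario_preset("null", n=300, seed=11))
    return data


@pytest.fixture
def crossover_trial():
    """Trial with a genuine benefitting subgroup (optimum reversed)."""
    return generate_trial(scenario_preset("crossover", n=2000, seed=5))


@pytest.fixture
def glm_truth_scenario():
    """Scenario whose outcome is exactly logistic-linear in (X, T)."""
    return SimScenario(
        n=400, d=3, baseline_coefs=np.array([0.8, -0.6, 0.4]),
        treat_main=-0.4, teh_kind="none", seed=2,
    )
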