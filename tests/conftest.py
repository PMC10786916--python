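import numpy as np
import pytest

from cooppunish import (
    CategoryCounts,
    ConditionDesign,
    ParameterSet,
    aggregate_counts,
    simulate_experiment,
)

#: interior generating parameters for the two-condition design, at the
#: cooperation rates observed in the bilateral-punishment experiment
TRUE_PARAMS = {
    "cooperating-majority": ParameterSet(0.70, 0.50, 0.35, 0.15, 0.05),
    "defecting-majority": ParameterSet(0.56, 0.40, 0.28, 0.10, 0.05),
}


@pytest.fixture(scope="session")
def exp1_designs() -> list[ConditionDesign]:
    return [
        ConditionDesign("cooperating-majority", 0.6, 278, partner_punishes=True),
        ConditionDesign("defecting-majority", 0.4, 266, partner_punishes=True),
    ]


@pytest.fixture(scope="session")
def exp1_trials(exp1_designs):
    return simulate_experiment(exp1_designs, TRUE_PARAMS, seed=20240112)


@pytest.fixture(scope="session")
def exp1_counts(exp1_trials) -> CategoryCounts:
    return aggregate_counts(exp1_trials)


@pytest.fixture()
def one_condition_counts() -> CategoryCounts:
    """Hand-picked interior counts for a single condition."""
    return CategoryCounts(
        {"only": np.array([420, 380, 90, 210, 55, 745, 40, 160], dtype=float)}
    )
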