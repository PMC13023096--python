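import pytest

from stemboost import (
    CostParameters,
    StrategyParameters,
    build_transition_matrix,
    run_cohort,
)


@pytest.fixture(scope="session")
def noboost_params():
    return StrategyParameters.no_boost_base_case()


@pytest.fixture(scope="session")
def boost_params():
    return StrategyParameters.boost_base_case()


@pytest.fixture(scope="session")
def costs():
    return CostParameters()


@pytest.fixture(scope="session")
def base_traces(noboost_params, boost_params):
    """Base-case cohort traces (no-boost, boost): 10,000 patients, 96 cycles."""
    tr_nb = run_cohort(build_transition_matrix(noboost_params))
    tr_b = run_cohort(build_transition_matrix(boost_params))
    return tr_nb, tr_b
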