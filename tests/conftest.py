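import pytest

from htn_cea import base_case, run_psa, synthetic_life_table


@pytest.fixture(scope="session")
def params():
    return base_case()


@pytest.fixture(scope="session")
def lifetable():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def psa_result(params, lifetable):
    """One shared 10,000-iteration PSA at the base 5% discount rate."""
    return run_psa(params, lt=lifetable, n_iterations=10_000, seed=20100405)
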