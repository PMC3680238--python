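import pytest

import fluxscreen as fs


@pytest.fixture(scope="session")
def core_model():
    return fs.make_core_fixture()


@pytest.fixture(scope="session")
def core_cond():
    return fs.core_conditions()


@pytest.fixture(scope="session")
def core_ref(core_model, core_cond):
    """Parsimonious wild-type reference of the core fixture."""
    ref = fs.solve_pfba(core_model, core_cond)
    assert ref.optimal
    return ref


@pytest.fixture(scope="session")
def core_opts(core_ref):
    """Screen options with the viability floor at half the wild-type growth."""
    return fs.ScreenOptions(growth_min=0.5 * core_ref.objective_value)
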