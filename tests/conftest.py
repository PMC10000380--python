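import pytest

from oxyloop import compute_metrics, run_scenario
from oxyloop.fuzzy import default_system
from oxyloop.morphology import load_generation_table, morphology_frame
from oxyloop.simulate import MRAC_GAMMA_SWEEP, scenario_library


@pytest.fixture(scope="session")
def library():
    return scenario_library()


@pytest.fixture(scope="session")
def generation_table():
    return load_generation_table()


@pytest.fixture(scope="session")
def computed_morphology(generation_table):
    return morphology_frame(generation_table)


@pytest.fixture(scope="session")
def fuzzy_system():
    return default_system()


@pytest.fixture(scope="session")
def track95_result(library):
    return run_scenario(library["track_95"])


@pytest.fixture(scope="session")
def track90_result(library):
    return run_scenario(library["track_90"])


@pytest.fixture(scope="session")
def mrac_sweep_metrics(library):
    """Metrics of the plain-MRAC runs over the shipped adaptation-gain grid."""
    out = {}
    for g in MRAC_GAMMA_SWEEP:
        res = run_scenario(library[f"mrac_gamma_{g:g}"])
        out[g] = compute_metrics(res)
    return out
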