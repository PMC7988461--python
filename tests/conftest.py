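import pytest
from hypothesis import settings

from eadsa import (
    InstrumentModel,
    build_default_registry,
    default_ledger,
    quantify_simulated_run,
    scenario_preset,
    simulate_run,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def ledger():
    return default_ledger()


@pytest.fixture(scope="session")
def srm_free_run(registry):
    """Noiseless pooled-plasma-like run, shared across tests."""
    return simulate_run(
        scenario_preset("SRM1950_like"), mix_volume_ml=0.05,
        hydrolysed=False, seed=11, registry=registry,
    )


@pytest.fixture(scope="session")
def srm_free_report(registry, srm_free_run):
    return quantify_simulated_run(srm_free_run, registry).set_index("analyte")
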