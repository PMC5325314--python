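import numpy as np
import pytest

from chankin import scenarios as sn


@pytest.fixture(scope="session")
def base_scenario():
    """Reference constant-substrate scenario: all gammas 1, S = 90 nM,
    all enzyme totals 50 nM."""
    return sn.mapk_scenario()


@pytest.fixture(scope="session")
def base_params(base_scenario):
    return base_scenario.params


@pytest.fixture(scope="session")
def channeled_params(base_params):
    """Fully channeled system (no single enzymes)."""
    return base_params.with_totals(E1_tot=0.0, E2_tot=0.0)


@pytest.fixture(scope="session")
def nonchanneled_params(base_params):
    """Pure non-channeled cascade (no complexes)."""
    return base_params.with_totals(E12_tot=0.0)


@pytest.fixture(scope="session")
def small_ensemble():
    """Small seeded random parameter ensemble for property checks."""
    return sn.random_ensemble(12, seed=2024)
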