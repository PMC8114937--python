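import numpy as np
import pytest

from odzrates import (
    FractionationSet,
    IsotopeState,
    StoichiometryParams,
    default_scenario,
    generate_profile_dataset,
)


@pytest.fixture(scope="session")
def stoich():
    return StoichiometryParams()


@pytest.fixture(scope="session")
def alphas():
    return FractionationSet()


@pytest.fixture(scope="session")
def unit_alphas():
    return FractionationSet.no_fractionation()


@pytest.fixture(scope="session")
def iso():
    return IsotopeState(r_no2=0.0035, r_no3=0.0038)


@pytest.fixture(scope="session")
def clean_scenario():
    """Default scenario with all noise switched off."""
    return default_scenario(
        seed=0, conc_noise_sd=0.0, delta_noise_sd=0.0,
        tracer_noise_sd_nM=0.0, kinetics_noise_frac=0.0,
    )


@pytest.fixture(scope="session")
def clean_profile(clean_scenario):
    """Noise-free forward-modelled profile plus its ground-truth rates."""
    return generate_profile_dataset(clean_scenario)


@pytest.fixture(scope="session")
def transport(clean_scenario):
    return clean_scenario.transport


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
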