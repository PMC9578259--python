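import pytest

from redoxferm import (
    BiomassParameters,
    calibrate_biomass_params,
    default_registry,
)

# Wild-type reference chemostat observations (glucose-limited, D = 0.025 1/h):
# glycerol/biomass 8.1 mmol/g, biomass yield 14.2 g/mol substrates.
REFERENCE_GLYCEROL_PER_BIOMASS = 8.1
REFERENCE_BIOMASS_YIELD = 14.2
REFERENCE_DILUTION_RATE = 0.025


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_params():
    return BiomassParameters()


@pytest.fixture(scope="session")
def calibrated_params():
    """Biomass parameters anchored to the reference-strain chemostat."""
    return calibrate_biomass_params(
        REFERENCE_GLYCEROL_PER_BIOMASS,
        REFERENCE_BIOMASS_YIELD,
        REFERENCE_DILUTION_RATE,
    )
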