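import pytest

from aqhia.synthetic import SimulationConfig


@pytest.fixture
def two_year_config() -> SimulationConfig:
    """Reference/comparison years only: keeps generated series small and fast."""
    return SimulationConfig(seed=7, years=(2013, 2017))


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """Deterministic concentrations: every daily value equals the annual target."""
    return SimulationConfig(
        seed=7, years=(2013, 2017), noise_cv=0.0, seasonal_amplitude_fraction=0.0
    )
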