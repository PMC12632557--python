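import numpy as np
import pytest

from argokit.synthetic import (
    CohortDesign,
    KineticsModel,
    NeuronPreset,
    NoiseModel,
    OpticsModel,
    SyntheticConfig,
)


@pytest.fixture
def noise_off() -> NoiseModel:
    return NoiseModel.off()


@pytest.fixture
def small_design() -> CohortDesign:
    return CohortDesign(
        pulse_age=2.0,
        chase_times=(2.0, 3.0, 4.0, 5.0),
        n_animals_per_timepoint=4,
        pulse_delay_h=0.0,
    )


@pytest.fixture
def quiet_config(small_design, noise_off) -> SyntheticConfig:
    """Deterministic small cohort: no scatter, no pulse lag."""
    return SyntheticConfig(design=small_design, noise=noise_off)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
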