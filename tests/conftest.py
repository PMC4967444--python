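import numpy as np
import pytest

from synovadce import LTR, STANDARD, AIF, make_population_aif
from synovadce.config import PopulationConfig, RunConfig


@pytest.fixture(scope="session")
def std_aif() -> AIF:
    return make_population_aif(protocol=STANDARD)


@pytest.fixture(scope="session")
def ltr_aif() -> AIF:
    return make_population_aif(protocol=LTR)


@pytest.fixture()
def boxcar_aif() -> AIF:
    """cp = 1 on [0, 60 s], 0 after, on a 0.1 s grid out to 120 s."""
    t = np.round(np.arange(0.0, 120.0001, 0.1), 10)
    return AIF(times_s=t, cp=np.where(t <= 60.0, 1.0, 0.0))


@pytest.fixture()
def tiny_config() -> RunConfig:
    """Small, fast configuration for end-to-end pipeline tests: 2 subjects,
    ~9-voxel synovium masks on an 8x8x2 grid."""
    return RunConfig(
        n_subjects=2,
        grid_shape=(8, 8, 2),
        population=PopulationConfig(volume_mean_mm3=60.0, volume_sd_mm3=15.0,
                                    noise_sd=0.5, voxel_jitter_cv=0.05),
        seed=7,
    )
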