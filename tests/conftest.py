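import numpy as np
import pytest

from strokepwi.synth import SynthConfig, generate_perfusion_series


@pytest.fixture(scope="session")
def small_config():
    """A small, quiet cohort configuration shared across tests."""
    return SynthConfig(n_patients=12, n_timepoints=20,
                       volume_shape=(6, 16, 16), lesion_radius=(1.5, 3, 3),
                       bolus_onset_nt=6.0, bolus_delay_lt=3.0, seed=7)


@pytest.fixture(scope="session")
def series_roi(small_config):
    return generate_perfusion_series(small_config)


@pytest.fixture(scope="session")
def noisefree_series_roi():
    cfg = SynthConfig(n_patients=1, n_timepoints=20, volume_shape=(6, 16, 16),
                      lesion_radius=(1.5, 3, 3), bolus_onset_nt=6.0,
                      bolus_delay_lt=3.0, noise_sd=0.0, seed=3)
    return generate_perfusion_series(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
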