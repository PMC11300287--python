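import numpy as np
import pytest

from cshdwi import PipelineConfig, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240723)


@pytest.fixture
def small_sim_config():
    """A desk-scale study: 12 patients per cohort, small lesions."""
    return SimulationConfig(
        n_patients=12, lesion_size_range=(30, 80), seed=11,
    )


@pytest.fixture
def exact_recovery_config():
    """Noise-free ideal-mode mirrored cohorts with known center biases."""
    return SimulationConfig(
        n_patients=20, noise_sigma=0.0, signal_mode="ideal",
        target_mode="mirror", bias_adc=1.2, bias_fbv=0.65, seed=5,
    )


@pytest.fixture
def small_pipeline_config(small_sim_config):
    return PipelineConfig(sim=small_sim_config)
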