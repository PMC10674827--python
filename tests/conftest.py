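import numpy as np
import pytest

from fieldscale.io import PipelineConfig
from fieldscale.pipeline import run_pipeline
from fieldscale.synthetic import SimConfig, simulate_field

ZERO_NOISE = dict(reflectance_noise_sd=0.0, trace_noise_sd=0.0,
                  device_offset_sd=0.0, meteo_noise_sd=0.0,
                  rwc_noise_sd=0.0, spad_noise_sd=0.0, yield_noise_scale=0.0)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Trial with every noise SD at zero: downstream indices must equal their
    generating parameters exactly (up to pixel quantization)."""
    return simulate_field(SimConfig(seed=11, **ZERO_NOISE))


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default trial (paper-style monitoring: five
    traces on one plot per treatment)."""
    return run_pipeline(sim_config=SimConfig(seed=7),
                        config=PipelineConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
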