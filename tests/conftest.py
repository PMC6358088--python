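import numpy as np
import pytest

from lulcpipe.synthetic import (
    SceneConfig, default_signature, generate_ancillary, generate_truth,
    synthesize_stack,
)


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(grid_rows=30, grid_cols=30, year_start=2001,
                       year_end=2006, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_stack(small_config, small_truth):
    sig = default_signature(small_config.noise_sd)
    return synthesize_stack(small_truth, sig, small_config)


@pytest.fixture(scope="session")
def small_ancillary(small_config, small_truth):
    return generate_ancillary(small_truth, small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Noise- and cloud-free variant of the small scene."""
    return SceneConfig(grid_rows=20, grid_cols=20, year_start=2001,
                       year_end=2003, cloud_prob=0.0, noise_sd=0.0,
                       seed=7)


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return generate_truth(clean_config)


@pytest.fixture(scope="session")
def clean_stack(clean_config, clean_truth):
    sig = default_signature(0.03)
    return synthesize_stack(clean_truth, sig, clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
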