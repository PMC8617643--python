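import warnings

import pytest

from mycometab.simulate import SyntheticConfig, simulate_dataset
from mycometab.stages import make_stage_design

warnings.filterwarnings("ignore", message="dropping .* zero-variance")


@pytest.fixture(scope="session")
def design():
    return make_stage_design()


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across read-only tests."""
    cfg = SyntheticConfig(seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise, artifact-free dataset: observed values equal planted means."""
    cfg = SyntheticConfig(
        seed=7, sigma_bio=0.0, dropout_rate=0.0, outlier_rate=0.0, structural_rate=0.0
    )
    return simulate_dataset(cfg)
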