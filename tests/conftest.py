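import numpy as np
import pytest
from hypothesis import settings

from licfret.simulate import DatasetConfig, Photophysics, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def photo():
    return Photophysics()


@pytest.fixture(scope="session")
def orc_dataset(photo):
    """Small WT ORC-alone dataset (bent/unbent FRET pair, 1-s frames)."""
    cfg = DatasetConfig(variant="ORC_only", n_molecules=80, tmax_s=600.0,
                        frame_dt_s=1.0, protocol="continuous_green", seed=42,
                        photophysics=photo, nonspecific_fraction=0.02)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def mcm_dataset(photo):
    """Small MCM•+51 helicase-loading dataset (0.25-s frames)."""
    cfg = DatasetConfig(variant="MCM_51", n_molecules=60, tmax_s=250.0,
                        frame_dt_s=0.25, protocol="alternating", seed=42,
                        photophysics=photo)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
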