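import numpy as np
import pytest

from rmfm import MFMParams, SCMatrix, SimulationConfig, make_synthetic_sc


@pytest.fixture(scope="session")
def small_sc() -> SCMatrix:
    """Seeded 6-region connectome shared by simulation tests."""
    return make_synthetic_sc(6, n_modules=2, seed=42)


@pytest.fixture(scope="session")
def small_params() -> MFMParams:
    return MFMParams.uniform(6, w=0.5, I=0.3, G=1.0, sigma=0.001)


@pytest.fixture(scope="session")
def quick_cfg() -> SimulationConfig:
    """Short protocol for tests that only need a valid FC, not a stable one."""
    return SimulationConfig(duration=80.0, burn_in=8.0, tr=0.36, seed=0)


@pytest.fixture(scope="session")
def committed_dir():
    from pathlib import Path

    return Path(__file__).parent / "data"
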