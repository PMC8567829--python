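import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mdmf import (
    Concentrations,
    ModelParameters,
    SimulationConfig,
    StateTrajectory,
    synthetic_connectome,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def conc() -> Concentrations:
    return Concentrations()


@pytest.fixture(scope="session")
def small_connectome():
    """A 6-region synthetic connectome for fast network tests."""
    return synthetic_connectome(6, seed=11, density=0.8)


def make_trajectory(SE: np.ndarray, dt_ms: float = 1.0, labels=None) -> StateTrajectory:
    """Wrap a hand-crafted neural series (samples x regions) as a trajectory."""
    SE = np.asarray(SE, dtype=float)
    n_samples, n = SE.shape
    time = np.arange(n_samples) * dt_ms
    zeros = np.zeros_like(SE)
    cfg = SimulationConfig(duration=n_samples * dt_ms, dt=dt_ms, record_stride=1)
    return StateTrajectory(
        time=time, SE=SE, SI=zeros, J=np.ones_like(SE),
        rE=zeros, rI=zeros, config=cfg,
        params=ModelParameters(), conc=Concentrations(), labels=labels,
    )
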