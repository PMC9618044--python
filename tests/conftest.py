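import numpy as np
import pytest

from ringsim import ModelParams, RingState
from ringsim.state import Filament, MyosinCluster


@pytest.fixture
def params() -> ModelParams:
    """Default (normal intact-ring) parameters."""
    return ModelParams()


@pytest.fixture
def small_ring_params() -> ModelParams:
    """A small, sparse ring that steps quickly in tests."""
    return ModelParams(R=1.0, rho_for=3.0, rho_myo=2.0, rho_x=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def single_filament_state(params: ModelParams, n_sub: int = 2,
                          axis=(0.0, 0.0, -1.0)) -> RingState:
    """One straight filament with its formin on the anchor sphere at +x."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    r0 = np.array([params.R - params.d_for_anchor, 0.0, 0.0])
    pts = r0[None, :] + params.l0 * np.arange(n_sub)[:, None] * axis[None, :]
    st = RingState()
    st.filaments = [Filament(pts)]
    return st


def anchored_myosin(params: ModelParams, arc_phi: float = 0.0) -> MyosinCluster:
    r = params.R - params.d_myo_anchor
    return MyosinCluster(np.array([r * np.cos(arc_phi), r * np.sin(arc_phi), 0.0]))
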