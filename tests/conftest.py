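import numpy as np
import pytest

from bacon import ModelParams


@pytest.fixture(scope="session")
def params():
    """Reference parameter set (full size)."""
    return ModelParams()


@pytest.fixture(scope="session")
def small_params():
    """A reduced hippocampus with the reference attribute world.

    Only the cell count is scaled down; the evidence model (N_A, N_Gen,
    N_Ctx and all thresholds) is untouched, so controller behaviour is
    comparable while sessions run fast.
    """
    return ModelParams(N_Hipp=2000)


@pytest.fixture(scope="session")
def tiny_params():
    """A tiny fully-checkable world for enumeration/brute-force oracles."""
    return ModelParams(
        N_Ctx=60,
        N_Hipp=200,
        N_A=20,
        N_Gen=10,
        F=12,
        K=12,
        K_0=4,
        Z_0=9,
        ThrshCtx=8,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
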