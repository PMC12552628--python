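import numpy as np
import pytest

from classim import ObjectImage, ScreenParams, bars_target, simulate_incoherent_stack


@pytest.fixture(scope="session")
def small_incoherent_stack():
    """8x8 speckle stack with ground-truth PSFs, shared across tests."""
    rng = np.random.default_rng(2)
    obj = ObjectImage(values=rng.random((8, 8)))
    stack, psfs = simulate_incoherent_stack(
        obj, 10, ScreenParams(corr_len_px=2, rms_rad=2 * np.pi), seed=3
    )
    return obj, stack, psfs


@pytest.fixture(scope="session")
def bars64():
    return bars_target(64)
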