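import numpy as np
import pytest

from biofilm_flowcell.synthetic import ImagingLayout, SyntheticParams


@pytest.fixture(scope="session")
def reduced_layout() -> ImagingLayout:
    """Small simulation windows (128 px, 12 z-slices, 45 cycles)."""
    return ImagingLayout.reduced(flow_rate=0.1, window_px=128, z_slices=12, n_cycles=45)


@pytest.fixture(scope="session")
def quiet_params() -> SyntheticParams:
    """Reduced-window generator with blur, noise and shedding disabled."""
    return SyntheticParams.reduced_window_defaults(
        rng_seed=11, detachment_rate=0.0
    ).noise_free()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
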