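import numpy as np
import pytest

from myoviability.synthetic import SyntheticSectionSpec


@pytest.fixture
def small_spec():
    """A fast-to-render section spec for unit tests (not study conditions)."""
    return SyntheticSectionSpec(
        width_px=160,
        height_px=160,
        n_fibers=20,
        interstitium_width_px=4.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
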