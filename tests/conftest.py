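import numpy as np
import pytest

from chemoscale.mwc_cluster import TrimerParams


@pytest.fixture
def sharp_trimer() -> TrimerParams:
    """Attractant trimer with well-separated Kds and a -6 kBT offset: the
    shared parameter set of the cooperativity-regime comparisons."""
    return TrimerParams(
        e_on=-6.0, e_off=0.0, kd_on=(0.5, 0.5, 0.5), kd_off=(0.02, 0.02, 0.02)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
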