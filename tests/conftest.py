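import numpy as np
import pytest

from jsbseg import JohnsonSBParams, make_phantom, segment_slice
from jsbseg.mixture_models import EMConfig


def jsb_with_median(median: float, delta: float, xi: float = -0.5, lam: float = 256.0) -> JohnsonSBParams:
    """S_B component with its median pinned at a chosen gray value."""
    u = (median - xi) / lam
    gamma = -delta * np.log(u / (1.0 - u))
    return JohnsonSBParams(gamma, delta, xi, lam)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(seed=0)


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    """One K=13 segmentation of the default phantom, shared across tests."""
    result = segment_slice(default_phantom.image, config=EMConfig(K=13))
    return default_phantom, result
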