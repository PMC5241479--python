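import numpy as np
import pytest

from tonguelab import SyntheticSpec, make_tongue_image


@pytest.fixture
def default_fixture():
    """Default synthetic tongue image with ground-truth masks."""
    return make_tongue_image(SyntheticSpec(seed=7))


@pytest.fixture
def flat_fixture():
    """Zero-texture, zero-noise tongue: two flat color regions."""
    return make_tongue_image(SyntheticSpec(texture_amplitude=0.0, noise_sigma=0.0, seed=7))


def iou(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else float("nan")
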