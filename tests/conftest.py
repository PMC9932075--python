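import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from deepaction.project import BehaviorSet


@pytest.fixture
def behavior_set():
    return BehaviorSet(["rest", "walk", "run"])


@pytest.fixture
def textured_image():
    """Smooth random texture: well-conditioned for optical-flow estimation."""
    rng = np.random.default_rng(42)
    img = gaussian_filter(rng.random((96, 96)), sigma=2.0)
    img = (img - img.min()) / (img.max() - img.min())
    return img
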