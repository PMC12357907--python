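import numpy as np
import pytest

from oligomorph.image import ChannelImage
from oligomorph.synthetic import SceneParams, generate_scene, render_channels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_scene():
    """Noise-free MBP scene at generator defaults."""
    return generate_scene(SceneParams(), seed=7)


@pytest.fixture
def clean_channels(clean_scene):
    return render_channels(clean_scene)


def make_image(pixels, channel="MBP", **kw) -> ChannelImage:
    return ChannelImage(np.asarray(pixels), channel=channel, **kw)
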