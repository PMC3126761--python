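import numpy as np
import pytest

from poremetry import CalibratedImage, PipelineConfig, preprocess, segment
from poremetry.fixtures import (generate_fibril_network, render_tem)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def network_phantom():
    """Default 512^2 fibril-network phantom, rendered with default corruption."""
    ph = generate_fibril_network((512, 512), seed=1)
    return render_tem(ph, seed=2)


@pytest.fixture(scope="session")
def segmented_network(network_phantom, cfg):
    """The rendered network phantom taken through preprocess + segment."""
    img = CalibratedImage(network_phantom.rendered,
                          network_phantom.pixel_pitch_nm)
    return segment(preprocess(img))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
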