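import numpy as np
import pytest

from rfseg import PhantomSpec, PipelineConfig, make_phantom, segment
from rfseg.skull_strip import strip_skull


@pytest.fixture(scope="session")
def default_phantom():
    """Default 256x256 phantom (seed 42) with its ground truth."""
    image, truth, brain = make_phantom(PhantomSpec(seed=42))
    return image, truth, brain


@pytest.fixture(scope="session")
def phantom_segmentation(default_phantom):
    """Full-pipeline segmentation of the default phantom (computed once)."""
    image, truth, brain = default_phantom
    labels, reports = segment(image, PipelineConfig(seed=42))
    return labels, reports


@pytest.fixture(scope="session")
def phantom_mask(default_phantom):
    """Skull-strip output on the default phantom."""
    image, _, _ = default_phantom
    mask, trace = strip_skull(image)
    return mask, trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
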