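import dataclasses

import numpy as np
import pytest

import planktonflow as pf


@pytest.fixture(scope="session")
def default_scene():
    """The reference study scene: 20 frames, 128x128, 8 fast blobs, sigma=1, seed 7."""
    return pf.generate_scene(pf.SceneConfig())


@pytest.fixture(scope="session")
def default_detections(default_scene):
    frames, _ = default_scene
    return pf.detect_sequence(frames, pf.DetectorConfig())


@pytest.fixture(scope="session")
def stride2_detections(default_scene):
    frames, _ = default_scene
    cfg = dataclasses.replace(pf.DetectorConfig(), pixel_stride=2)
    return pf.detect_sequence(frames, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
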