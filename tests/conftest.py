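import numpy as np
import pytest

from tasselrow import PipelineConfig, PreprocessParams, SceneParams, TrackerParams
from tasselrow.synthetic import scene_config


@pytest.fixture
def pp() -> PreprocessParams:
    return PreprocessParams()


@pytest.fixture
def tp() -> TrackerParams:
    return TrackerParams()


@pytest.fixture
def cfg() -> PipelineConfig:
    """Pipeline config matched to synthetic working-frame scenes."""
    return scene_config()


@pytest.fixture
def clean_mask_scene():
    """A noise-free binary scene with its ground truth."""
    from tasselrow import generate_mask_scene

    return generate_mask_scene(SceneParams(seed=11, impulse_noise=0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
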