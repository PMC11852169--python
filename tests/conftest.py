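import numpy as np
import pytest

from funduslab import pipeline, synthetic
from funduslab.config import load_config


@pytest.fixture(scope="session")
def run_cfg():
    return load_config(None, seed=0)


@pytest.fixture(scope="session")
def scene():
    """One default synthetic scene shared across tests."""
    return synthetic.generate_scene(seed=7)


@pytest.fixture(scope="session")
def labeled_scene(scene, run_cfg):
    """The shared scene run through the geometric labeler."""
    return pipeline.label_gray(scene.image, run_cfg)


@pytest.fixture(scope="session")
def clean_scene():
    cfg = synthetic.SceneConfig(n_microaneurysms=0, n_hemorrhages=0,
                                n_hard_exudates=0, n_soft_exudates=0,
                                n_faint=0)
    return synthetic.generate_scene(cfg, seed=97)


def flat_gray(shape=(64, 64), value=0.5, fov_margin=10):
    from funduslab.imaging import GrayImage
    px = np.full(shape, value, dtype=float)
    fov = np.zeros(shape, dtype=bool)
    fov[fov_margin:shape[0] - fov_margin, fov_margin:shape[1] - fov_margin] = True
    return GrayImage(pixels=px, fov=fov)
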