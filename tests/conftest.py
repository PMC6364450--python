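"""Shared fixtures: synthetic rig, scenes and the full recovery study."""

import logging

import numpy as np
import pytest

from stressphen import io_cli, synthscene as ss

logging.getLogger("stressphen").setLevel(logging.ERROR)

STUDY_SEED = 1
STUDY_SCALE = 0.5


@pytest.fixture(scope="session")
def rig():
    return ss.make_rig(scale=STUDY_SCALE)


@pytest.fixture(scope="session")
def rig_full():
    return ss.make_rig(scale=1.0)


@pytest.fixture(scope="session")
def effects():
    return ss.StressEffectModel()


@pytest.fixture(scope="session")
def plan():
    return ss.make_treatment_plan()


@pytest.fixture(scope="session")
def panel(rig):
    return ss.default_panel_spec(rig)


@pytest.fixture(scope="session")
def config():
    return io_cli.PipelineConfig()


@pytest.fixture(scope="session")
def frameset(plan, rig, effects):
    """One mid-growth rendered box-date with its ground truth."""
    scene = ss.grow_canopy(plan[7], 42, effects, seed=STUDY_SEED)
    return ss.render_frameset(scene, rig, effects, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def default_study(plan, rig, effects, config):
    """Full 30-box x 16-date synthetic study at reduced image size."""
    traits, labels = io_cli.run_study(plan, ss.default_das_schedule(), rig,
                                      effects, seed=STUDY_SEED, config=config)
    return traits, labels


@pytest.fixture(scope="session")
def null_study(plan, rig, config):
    """Same study with all stress effect sizes set to zero."""
    traits, labels = io_cli.run_study(plan, ss.default_das_schedule(), rig,
                                      ss.StressEffectModel.null(),
                                      seed=STUDY_SEED, config=config)
    return traits, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng, n=500, with_height=True):
    """Random spectral point cloud for property tests."""
    from stressphen.optics import SpectralPointCloud, default_band_wavelengths
    xyz = np.column_stack([rng.uniform(-0.2, 0.2, n), rng.uniform(-0.1, 0.1, n),
                           rng.uniform(0.7, 1.1, n)])
    cloud = SpectralPointCloud(
        xyz=xyz, rgb=rng.uniform(0, 0.8, (n, 3)), bands=rng.uniform(0, 0.8, (n, 25)),
        wavelengths=default_band_wavelengths(),
        height=rng.uniform(-0.02, 0.3, n) if with_height else None)
    if with_height:
        h = np.asarray(cloud.height)
        h[rng.random(n) < 0.1] = np.nan
        cloud.height = h
    return cloud
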