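import numpy as np
import pytest

from petseg import phantom, pipeline
from petseg.mesh_graph import build_sphere_mesh
from petseg.pipeline import SegmentationConfig


@pytest.fixture(scope="session")
def mesh_l0():
    return build_sphere_mesh(0)


@pytest.fixture(scope="session")
def mesh_l1():
    return build_sphere_mesh(1)


@pytest.fixture(scope="session")
def mesh_l3():
    return build_sphere_mesh(3)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced problem size for pipeline tests: 258 columns x 30 nodes."""
    return SegmentationConfig(radius_mm=30.0, mesh_level=3)


@pytest.fixture(scope="session")
def sphere_scene():
    """Noise-free 10 mm sphere, 4:1 contrast, FWHM 5 mm; (vol, truth, center)."""
    return phantom.single_sphere_scene(radius_mm=10.0, contrast_ratio=4.0,
                                       psf_fwhm_mm=5.0)


@pytest.fixture(scope="session")
def sphere_result(sphere_scene, small_cfg):
    """Base segmentation of the sphere scene at reduced size (read-only)."""
    vol, truth, center = sphere_scene
    return pipeline.segment(vol, center, small_cfg)


@pytest.fixture
def sphere_session(sphere_scene, small_cfg):
    """Fresh interactive session on the sphere scene (mutable per test)."""
    vol, _, center = sphere_scene
    session, report = pipeline.start_session(vol, center, small_cfg)
    return session, report


# Deterministic property-based testing: fixed example generation, no on-disk
# example database.
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, database=None)
_hyp_settings.load_profile("deterministic")
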