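import numpy as np
import pytest

from tfusnav import (MaterialTable, NucleusSpec, PhantomSpec, TransducerPose,
                     TransducerSpec, make_phantom, mesh_scalp,
                     precompute_library, solve_beam)
from tfusnav.config import SolverSettings

# Reduced problem sizes keep full-physics pipeline runs tractable while
# preserving the geometry ratios of a human study: a 46 mm spherical
# "head" with a 6 mm-thick skull shell, F = 55 mm / 61 mm-aperture
# transducer at a 9 mm gel pad.
SPHERE_R = 46.0
F55 = TransducerSpec(frequency=650e3, aperture_diameter=61.0,
                     focal_distance=55.0, standoff=9.0)
#: small fast transducer for tests whose substance is not tied to the
#: clinical geometry (determinism, navigation, plumbing)
SMALL = TransducerSpec(frequency=650e3, aperture_diameter=30.0,
                       focal_distance=40.0, standoff=5.0)

#: no-skull material table — soft-tissue endpoint is literally water, so a
#: porosity-1 phantom is the exact water-propagation limit
WATER_TABLE = MaterialTable(rho_brain=1000.0, rho_bone=1908.0,
                            c_brain=1500.0, c_bone=3514.0,
                            alpha_brain=1e-12, alpha_bone=54.6)


def sphere_phantom_spec(**overrides):
    base = dict(outer_radii=(SPHERE_R,) * 3, skull_outer_radii=(44.0,) * 3,
                skull_inner_radii=(38.0,) * 3, skull_porosity=0.3,
                skull_porosity_variation=0.0, voxel_size=1.5,
                nuclei=(NucleusSpec(10, (0.0, 0.0, 0.0), (6.0, 6.0, 6.0),
                                    "center-target"),),
                seed=7)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def sphere_head():
    """Spherical phantom, uniform 0.3-porosity skull shell, centered nucleus."""
    return make_phantom(sphere_phantom_spec())


@pytest.fixture(scope="session")
def sphere_mesh(sphere_head):
    return mesh_scalp(sphere_head.head_mask, 100, sphere_head.affine)


@pytest.fixture(scope="session")
def sphere_library(tmp_path_factory, sphere_head, sphere_mesh):
    """Skull-aware F55 beam library over every face of the sphere phantom."""
    path = tmp_path_factory.mktemp("lib") / "beams.h5"
    precompute_library(sphere_head, sphere_mesh, F55, path,
                       settings=SolverSettings(), config_hash="sphere-f55")
    return path


@pytest.fixture(scope="session")
def small_head():
    """Smaller sphere phantom matched to the fast SMALL transducer."""
    return make_phantom(sphere_phantom_spec(
        outer_radii=(33.0,) * 3, skull_outer_radii=(31.0,) * 3,
        skull_inner_radii=(26.0,) * 3,
        nuclei=(NucleusSpec(10, (0.0, 0.0, 0.0), (5.0, 5.0, 5.0)),
                NucleusSpec(18, (0.0, 10.0, 6.0), (4.0, 4.0, 4.0)))))


@pytest.fixture(scope="session")
def small_mesh(small_head):
    return mesh_scalp(small_head.head_mask, 48, small_head.affine)


@pytest.fixture(scope="session")
def small_library(tmp_path_factory, small_head, small_mesh):
    path = tmp_path_factory.mktemp("smalllib") / "beams.h5"
    precompute_library(small_head, small_mesh, SMALL, path,
                       settings=SolverSettings(), config_hash="small")
    return path


@pytest.fixture(scope="session")
def water_beam_f65():
    """Full-resolution water solve of the F = 65 mm clinical geometry."""
    spec = TransducerSpec(frequency=650e3, aperture_diameter=61.0,
                          focal_distance=65.0, standoff=0.0)
    pose = TransducerPose(0, np.zeros(3), np.array([0.0, 0.0, 1.0]))
    return solve_beam(pose, spec, None, keep_pressure=True), spec
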