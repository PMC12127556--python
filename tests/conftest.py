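import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from breqa import (
    BoneMotion,
    DeformationSpec,
    Ellipsoid,
    Geometry,
    PhantomSpec,
    VectorField,
    make_dvf,
    make_phantom,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251)


@pytest.fixture
def unit_cube_corners() -> np.ndarray:
    """The 8 corners of the unit cube (mm)."""
    return np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )


@pytest.fixture
def smooth_dvf(rng) -> VectorField:
    """A random smooth displacement field on an anisotropic grid."""
    from scipy.ndimage import gaussian_filter

    data = rng.normal(0, 1, (14, 12, 10, 3))
    for c in range(3):
        data[..., c] = gaussian_filter(data[..., c], sigma=2.0)
    data *= 3.0 / data.std()
    geom = Geometry(origin=(-10.0, 5.0, 0.0), spacing=(2.0, 1.5, 3.0))
    return VectorField(data, geom)


@pytest.fixture
def ellipsoid_phantom():
    """One ellipsoidal bone in a 32^3 volume, 2 mm voxels, no noise."""
    spec = PhantomSpec(
        shape=(32, 32, 32),
        spacing=(2.0, 2.0, 2.0),
        primitives=(Ellipsoid(center=(32.0, 32.0, 32.0), semi_axes=(18.0, 12.0, 10.0), label=1),),
        noise_sigma_hu=0.0,
    )
    return make_phantom(spec)


def random_rigid(rng, max_angle=0.3, max_shift=5.0):
    """A random proper rotation (rotvec up to max_angle rad) and translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.05, max_angle)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_shift, max_shift, 3)
    return R, t


def rigid_bone_case(seed=0, violations=None, amplitude=2.0):
    """Phantom with three differently shaped bones under per-bone rigid motion."""
    from breqa import Box, Cylinder

    spec = PhantomSpec(
        shape=(40, 40, 40),
        spacing=(2.0, 2.0, 2.0),
        primitives=(
            Ellipsoid(center=(20.0, 20.0, 20.0), semi_axes=(12.0, 8.0, 7.0), label=1),
            Cylinder(center=(56.0, 24.0, 40.0), radius=6.0, half_length=18.0, label=2),
            Box(center=(30.0, 56.0, 56.0), half_sizes=(9.0, 7.0, 6.0), label=3),
        ),
        noise_sigma_hu=0.0,
    )
    _, labels = make_phantom(spec)
    rng = np.random.default_rng(seed)
    motions = {}
    for label in (1, 2, 3):
        R, t = random_rigid(rng)
        motions[label] = BoneMotion(
            rotation_vec=tuple(Rotation.from_matrix(R).as_rotvec()),
            translation=tuple(t),
        )
    dspec = DeformationSpec(
        motions=motions,
        violations=violations or {},
        background_amplitude_mm=amplitude,
        seed=seed + 1,
    )
    dvf, truth = make_dvf(dspec, labels)
    return labels, dvf, truth
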