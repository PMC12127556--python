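"""Synthetic phantoms and deformation fields with known ground truth.

Real registrations provide no per-voxel truth, so correctness of the BRE
pipeline is established on phantoms: simple bone primitives (ellipsoids,
cylinders, boxes) rasterised into a CT-like volume, deformed by a field that
is exactly rigid inside every bone — optionally with a controlled rigidity
violation whose expected BRE is known in closed form — and smoothly random in
the soft tissue between them.

Everything is deterministic per seed, down to the bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grids import Geometry, LabelMap, ScalarVolume, VectorField
from .metrics import LandmarkSet
from .rigid import RigidTransform

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "Box",
    "PhantomSpec",
    "BoneMotion",
    "Violation",
    "DeformationSpec",
    "BoneTruth",
    "make_phantom",
    "make_dvf",
    "make_landmarks",
    "OverlapError",
]

# defaults emulating CT: soft tissue near water, cortical-bone-like density,
# mild acquisition noise
DEFAULT_BACKGROUND_HU = 0.0
DEFAULT_BONE_HU = 700.0
DEFAULT_NOISE_SIGMA_HU = 20.0


class OverlapError(ValueError):
    """Two bone primitives claim the same voxel; bones must be disjoint."""


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple  # world mm
    semi_axes: tuple  # mm
    label: int
    hu: float = DEFAULT_BONE_HU

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = (points - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sum(rel**2, axis=-1) <= 1.0


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder along ``axis`` (unit vector), emulating a long bone."""

    center: tuple
    radius: float  # mm
    half_length: float  # mm
    axis: tuple = (0.0, 0.0, 1.0)
    label: int = 1
    hu: float = DEFAULT_BONE_HU

    def contains(self, points: np.ndarray) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rel = points - np.asarray(self.center)
        along = rel @ axis
        radial = rel - along[..., None] * axis
        return (np.abs(along) <= self.half_length) & (
            np.linalg.norm(radial, axis=-1) <= self.radius
        )


@dataclass(frozen=True)
class Box:
    center: tuple
    half_sizes: tuple  # mm
    label: int = 1
    hu: float = DEFAULT_BONE_HU

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = np.abs(points - np.asarray(self.center))
        return np.all(rel <= np.asarray(self.half_sizes), axis=-1)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a phantom volume + label map."""

    shape: tuple = (48, 48, 48)
    spacing: tuple = (2.0, 2.0, 2.0)  # mm, CT-like
    origin: tuple = (0.0, 0.0, 0.0)
    primitives: tuple = ()
    background_hu: float = DEFAULT_BACKGROUND_HU
    noise_sigma_hu: float = DEFAULT_NOISE_SIGMA_HU
    seed: int = 0

    @property
    def geometry(self) -> Geometry:
        return Geometry(np.asarray(self.origin), np.asarray(self.spacing))


def _voxel_centers(geometry: Geometry, shape) -> np.ndarray:
    """(nx, ny, nz, 3) world coordinates of all voxel centres."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    )
    return geometry.world_from_index(idx)


def make_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, LabelMap]:
    """Rasterise the primitives into an intensity volume and label map.

    Primitives are tested against voxel-centre world coordinates; labels must
    be unique and the bones disjoint. Deterministic per seed.
    """
    geom = spec.geometry
    points = _voxel_centers(geom, spec.shape)
    labels = np.zeros(spec.shape, dtype=np.int32)
    intensity = np.full(spec.shape, float(spec.background_hu))
    seen = set()
    for prim in spec.primitives:
        if prim.label in seen:
            raise ValueError(f"duplicate primitive label {prim.label}")
        seen.add(prim.label)
        mask = prim.contains(points)
        if np.any(labels[mask] != 0):
            raise OverlapError(
                f"primitive with label {prim.label} overlaps an earlier primitive"
            )
        labels[mask] = prim.label
        intensity[mask] = prim.hu
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma_hu, spec.shape)
    return ScalarVolume(intensity, geom), LabelMap(labels, geom)


@dataclass(frozen=True)
class BoneMotion:
    """Per-bone rigid motion: rotation (axis-angle, rad) about the bone
    centroid plus a translation (mm)."""

    rotation_vec: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(np.asarray(self.rotation_vec)).as_matrix()


@dataclass(frozen=True)
class Violation:
    """Intra-bone rigidity violation applied before the rigid motion.

    mode:
      * ``none`` — exactly rigid; expected BRE 0.
      * ``scaling`` — isotropic scaling ``param = s`` about the bone centroid;
        expected BRE ``|s - 1| * mean||x_i - c||`` exactly.
      * ``shear`` — shear ``param = γ`` (x displaced along y) about the
        centroid; expected BRE from the affine closed form (optimal rotation
        via the SVD of scatter·Aᵀ on the generated voxels).
      * ``residual`` — constructed residual field of amplitude ``param = α``,
        orthogonal to the translational and linearised rotational modes
        (Σe_i = 0, Σ(x_i−c)×e_i = 0), so the identity stays the optimal fit
        to first order in α and the expected BRE is ``α * mean||e_i||``
        (accurate to O(α²)).
    """

    mode: str = "none"
    param: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "scaling", "shear", "residual"):
            raise ValueError(f"unknown violation mode {self.mode!r}")


@dataclass(frozen=True)
class DeformationSpec:
    """Recipe for a DVF over a label map: per-bone rigid motions, optional
    violations, and a smooth random soft-tissue field between the bones."""

    motions: dict = dc_field(default_factory=dict)  # label -> BoneMotion
    violations: dict = dc_field(default_factory=dict)  # label -> Violation
    background_amplitude_mm: float = 2.0
    background_scale_mm: float = 20.0
    blend_margin_mm: float = 6.0
    seed: int = 0


@dataclass(frozen=True)
class BoneTruth:
    """Ground truth for one generated bone."""

    label: int
    transform: RigidTransform  # the generating rigid motion, world frame
    mode: str
    param: float
    expected_bre: float  # mm


def _constructed_residual(xc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS residual field with zero net translation and zero net torque.

    Projects white noise off the constant modes and the three linearised
    rotation modes e_k × (x − c), leaving a perturbation for which the
    identity remains the optimal rigid fit (to first order, confirmed by the
    brute-force oracle in the tests).
    """
    n = xc.shape[0]
    e = rng.standard_normal((n, 3))
    basis = []
    for k in range(3):
        m = np.zeros((n, 3))
        m[:, k] = 1.0  # translation mode
        basis.append(m)
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        basis.append(np.cross(axis, xc))  # rotation mode
    for m in basis:
        norm2 = np.sum(m * m)
        if norm2 > 0:
            e = e - m * (np.sum(e * m) / norm2)
    rms = np.sqrt(np.mean(np.sum(e**2, axis=1)))
    return e / rms


def _optimal_rotation_for_affine(xc: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Proper rotation closest (least squares) to the affine map xc -> A xc."""
    H = xc.T @ (xc @ A.T)  # = scatter · Aᵀ accumulated over points
    U, _, Vt = np.linalg.svd(H)
    V = Vt.T
    d = np.sign(np.linalg.det(V @ U.T))
    return V @ np.diag([1.0, 1.0, d]) @ U.T


def make_dvf(
    spec: DeformationSpec, labels: LabelMap
) -> tuple[VectorField, dict[int, BoneTruth]]:
    """Build a DVF that is exactly per-bone rigid (plus any violation) inside
    each labelled bone and smoothly random outside.

    Inside a bone with centroid ``c``, motion ``(R, t)`` and violation map
    ``V`` (identity / scaling / shear / identity+residual), the deformed point
    is ``y = R (V(x) − c) + c + t``, i.e. displacement ``d = y − x``. Outside
    the bones, Gaussian-filtered white noise of the stated amplitude and
    correlation length is blended towards each bone's rigid field over
    ``blend_margin_mm`` so the field is continuous at bone surfaces while the
    intra-bone values stay exact.

    Returns the field (on the label-map grid) and per-bone ground truth with
    the effective world-frame rigid transform and the expected BRE.
    """
    geom = labels.geometry
    shape = labels.shape
    rng = np.random.default_rng(spec.seed)

    # smooth soft-tissue background field
    noise = rng.standard_normal(shape + (3,))
    if spec.background_amplitude_mm > 0:
        sigma_vox = np.asarray(spec.background_scale_mm) / geom.spacing
        for c in range(3):
            noise[..., c] = ndimage.gaussian_filter(noise[..., c], sigma=sigma_vox)
        std = noise.std()
        if std > 0:
            noise *= spec.background_amplitude_mm / std
        background = noise
    else:
        background = np.zeros(shape + (3,))

    points = _voxel_centers(geom, shape)
    field = background.copy()
    truth: dict[int, BoneTruth] = {}
    bone_mask = labels.labels > 0

    for label in labels.present_labels():
        motion = spec.motions.get(label, BoneMotion())
        violation = spec.violations.get(label, Violation())
        mask = labels.labels == label
        x = points[mask]
        c = x.mean(axis=0)
        xc = x - c
        R = motion.rotation_matrix()
        t = np.asarray(motion.translation, dtype=float)

        if violation.mode == "none":
            v = xc
            expected = 0.0
        elif violation.mode == "scaling":
            s = violation.param
            v = s * xc
            expected = abs(s - 1.0) * float(np.mean(np.linalg.norm(xc, axis=1)))
        elif violation.mode == "shear":
            A = np.eye(3)
            A[0, 1] = violation.param
            v = xc @ A.T
            Q = _optimal_rotation_for_affine(xc, A)
            expected = float(
                np.mean(np.linalg.norm(xc @ Q.T - xc @ A.T, axis=1))
            )
        else:  # residual
            e = _constructed_residual(xc, rng)
            alpha = violation.param
            v = xc + alpha * e
            expected = abs(alpha) * float(np.mean(np.linalg.norm(e, axis=1)))

        y = v @ R.T + c + t
        field[mask] = y - x
        # effective global rigid transform: y = R x + (c + t − R c)
        truth[label] = BoneTruth(
            label=label,
            transform=RigidTransform(R, c + t - R @ c),
            mode=violation.mode,
            param=violation.param,
            expected_bre=expected,
        )

    # blend the background towards each bone's rigid field near its surface
    if np.any(bone_mask) and not np.all(bone_mask):
        dist, nearest = ndimage.distance_transform_edt(
            ~bone_mask, sampling=geom.spacing, return_indices=True
        )
        outside = ~bone_mask
        near_field = field[nearest[0], nearest[1], nearest[2]]
        w = np.clip(dist / max(spec.blend_margin_mm, 1e-9), 0.0, 1.0)[..., None]
        field[outside] = (
            (1.0 - w) * near_field + w * background
        )[outside]

    return VectorField(field, geom), truth


_PRIMITIVE_TYPES = {"ellipsoid": Ellipsoid, "cylinder": Cylinder, "box": Box}


def phantom_spec_from_dict(data: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain (YAML-loaded) mapping."""
    prims = []
    for p in data.get("primitives", []):
        p = dict(p)
        kind = p.pop("type", "ellipsoid")
        if kind not in _PRIMITIVE_TYPES:
            raise ValueError(f"unknown primitive type {kind!r}")
        for key in ("center", "semi_axes", "half_sizes", "axis"):
            if key in p:
                p[key] = tuple(p[key])
        prims.append(_PRIMITIVE_TYPES[kind](**p))
    return PhantomSpec(
        shape=tuple(data.get("shape", (48, 48, 48))),
        spacing=tuple(data.get("spacing", (2.0, 2.0, 2.0))),
        origin=tuple(data.get("origin", (0.0, 0.0, 0.0))),
        primitives=tuple(prims),
        background_hu=float(data.get("background_hu", DEFAULT_BACKGROUND_HU)),
        noise_sigma_hu=float(data.get("noise_sigma_hu", DEFAULT_NOISE_SIGMA_HU)),
        seed=int(data.get("seed", 0)),
    )


def deformation_spec_from_dict(data: dict) -> DeformationSpec:
    """Build a DeformationSpec from a plain (YAML-loaded) mapping.

    Rotations may be given as ``rotation_deg`` (degrees, more natural in
    configs) or ``rotation_vec`` (radians).
    """
    motions = {}
    for label, m in (data.get("motions") or {}).items():
        m = dict(m or {})
        if "rotation_deg" in m:
            rotvec = tuple(np.deg2rad(np.asarray(m.pop("rotation_deg"), dtype=float)))
        else:
            rotvec = tuple(m.pop("rotation_vec", (0.0, 0.0, 0.0)))
        motions[int(label)] = BoneMotion(
            rotation_vec=rotvec,
            translation=tuple(m.pop("translation", (0.0, 0.0, 0.0))),
        )
    violations = {
        int(label): Violation(**(v or {}))
        for label, v in (data.get("violations") or {}).items()
    }
    return DeformationSpec(
        motions=motions,
        violations=violations,
        background_amplitude_mm=float(data.get("background_amplitude_mm", 2.0)),
        background_scale_mm=float(data.get("background_scale_mm", 20.0)),
        blend_margin_mm=float(data.get("blend_margin_mm", 6.0)),
        seed=int(data.get("seed", 0)),
    )


def make_landmarks(
    dvf: VectorField,
    n: int,
    jitter: float = 0.0,
    seed: int = 0,
    margin_voxels: float = 1.0,
) -> tuple[LandmarkSet, np.ndarray]:
    """Sample landmark pairs consistent with the DVF, plus isotropic Gaussian
    jitter of scale ``jitter`` (mm) on the moving points.

    Returns the landmark set and the per-landmark true TRE (the jitter norms;
    for a 3-D Gaussian their mean is ``jitter * sqrt(8/π)``).
    """
    if n < 1:
        raise ValueError("need n >= 1 landmarks")
    rng = np.random.default_rng(seed)
    shape = np.asarray(dvf.shape, dtype=float)
    lo = np.full(3, margin_voxels)
    hi = shape - 1 - margin_voxels
    idx = rng.uniform(lo, hi, size=(n, 3))
    fixed = dvf.geometry.world_from_index(idx)
    d, _ = dvf.sample(fixed)
    noise = jitter * rng.standard_normal((n, 3)) if jitter > 0 else np.zeros((n, 3))
    moving = fixed + d + noise
    true_tre = np.linalg.norm(noise, axis=1)
    return LandmarkSet(fixed, moving), true_tre
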