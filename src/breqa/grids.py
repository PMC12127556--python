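"""Regular-grid volumes with world-coordinate geometry.

Every quantity downstream of I/O — rigid fitting, the bone rigidity error,
landmark errors, Jacobian determinants — is computed in *world* coordinates,
in millimetres. A volume's geometry maps 0-based voxel indices ``i`` (voxel
centres) to world positions::

    x = origin + direction @ (i * spacing)

with ``spacing`` in mm/voxel and ``direction`` a 3x3 orthonormal matrix taking
index axes to world axes. This keeps the metric correct under anisotropic
voxels and oblique acquisitions.

Displacement fields follow the fixed→moving convention: a displacement ``d``
stored at a fixed-image position ``x`` means the registration maps ``x`` to
``y = x + d`` (world mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["Geometry", "VectorField", "LabelMap", "ScalarVolume"]

#: tolerance (in voxels) for deciding a point sits inside the grid extent
_INSIDE_TOL = 1e-9


@dataclass(frozen=True)
class Geometry:
    """World geometry of a regular 3-D grid (voxel-centre convention).

    Parameters
    ----------
    origin : (3,) array-like
        World position (mm) of the centre of voxel (0, 0, 0).
    spacing : (3,) array-like
        Voxel edge lengths (mm/voxel), strictly positive.
    direction : (3, 3) array-like, optional
        Orthonormal matrix mapping index axes to world axes. Identity by
        default (axis-aligned grid).
    """

    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        if not np.all(np.isfinite(origin)):
            raise ValueError("origin must be finite")
        ortho_err = np.linalg.norm(direction.T @ direction - np.eye(3))
        if ortho_err >= 1e-6:
            raise ValueError(
                f"direction matrix is not orthonormal (||D^T D - I|| = {ortho_err:.2e})"
            )
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "direction", direction)

    def world_from_index(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def index_from_world(self, xyz: np.ndarray) -> np.ndarray:
        """Map world positions (mm), shape (..., 3), to continuous indices."""
        xyz = np.asarray(xyz, dtype=float)
        # direction is orthonormal, so its inverse is the transpose
        return ((xyz - self.origin) @ self.direction) / self.spacing

    @property
    def affine(self) -> np.ndarray:
        """4x4 homogeneous index→world affine (voxel-centre convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing
        aff[:3, 3] = self.origin
        return aff

    def close_to(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


def _sample_linear(
    data: np.ndarray, geometry: Geometry, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear sampling of a (nx, ny, nz[, c]) array at world points.

    Returns the interpolated values and a boolean mask of points whose
    continuous index falls inside the grid extent (within a small tolerance).
    Outside points are still evaluated (clamped to the border) so callers can
    decide their own out-of-field policy.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    idx = geometry.index_from_world(points)
    shape = np.asarray(data.shape[:3])
    inside = np.all(
        (idx >= -_INSIDE_TOL) & (idx <= shape - 1 + _INSIDE_TOL), axis=1
    )
    coords = idx.T  # (3, M) as map_coordinates expects
    if data.ndim == 3:
        values = map_coordinates(data, coords, order=1, mode="nearest")
    else:
        values = np.stack(
            [
                map_coordinates(data[..., c], coords, order=1, mode="nearest")
                for c in range(data.shape[-1])
            ],
            axis=-1,
        )
    return values, inside


@dataclass(frozen=True)
class VectorField:
    """A deformation vector field: per-voxel 3-vectors of mm displacement.

    ``data`` has shape (nx, ny, nz, 3); component ``data[i, j, k]`` is the
    fixed→moving displacement, in world mm, at the voxel centre
    ``geometry.world_from_index([i, j, k])``.
    """

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError(
                f"vector field data must have shape (nx, ny, nz, 3), got {data.shape}"
            )
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def sample(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinearly interpolate displacements at world points (mm).

        Returns ``(displacements, inside)`` where ``displacements`` is (M, 3)
        and ``inside`` marks points within the field extent. At voxel centres
        the stored vector is reproduced exactly.
        """
        return _sample_linear(self.data, self.geometry, points)


@dataclass(frozen=True)
class ScalarVolume:
    """A scalar intensity volume (e.g. CT in HU) on a world-geometry grid."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"scalar volume must be 3-D, got shape {data.shape}")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def sample(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return _sample_linear(self.data, self.geometry, points)


@dataclass(frozen=True)
class LabelMap:
    """Integer-valued volume: 0 = background, each positive label one structure."""

    labels: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label map must be 3-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("label map values must be integers")
            labels = rounded.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("label map values must be >= 0")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> list[int]:
        """Sorted positive labels present in the map."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v > 0]

    def voxel_indices(self, label: int) -> np.ndarray:
        """(N, 3) integer indices of voxels carrying ``label``."""
        return np.argwhere(self.labels == label)
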