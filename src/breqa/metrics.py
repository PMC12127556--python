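"""Complementary registration-quality metrics evaluated alongside the BRE.

Rigidity is one axis of plausibility; a full QA pass also looks at image
similarity (MAE), landmark accuracy (TRE) and local volume change (Jacobian
determinant of the deformation). Rigidity implies incompressibility but not
the reverse: a sheared bone can keep det = 1 everywhere while its BRE is
clearly positive, which is why the BRE adds information over the Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .grids import LabelMap, ScalarVolume, VectorField

__all__ = [
    "LandmarkSet",
    "TREResult",
    "image_mae",
    "landmark_tre",
    "jacobian_determinant",
    "bre_tre_correlation",
    "GridMismatchError",
    "FieldTooSmallError",
    "DegenerateCorrelationError",
]


class GridMismatchError(ValueError):
    """Volumes live on different grids and were not resampled beforehand."""


class FieldTooSmallError(ValueError):
    """DVF too small for finite-difference gradients (< 3 voxels on an axis)."""


class DegenerateCorrelationError(ValueError):
    """Pearson correlation is undefined: one of the inputs has zero variance."""


@dataclass(frozen=True)
class LandmarkSet:
    """Paired landmarks: fixed-image and moving-image world positions (mm).

    Pairing is by list order; no point matching is attempted.
    """

    points_fixed: np.ndarray
    points_moving: np.ndarray

    def __post_init__(self) -> None:
        pf = np.atleast_2d(np.asarray(self.points_fixed, dtype=float))
        pm = np.atleast_2d(np.asarray(self.points_moving, dtype=float))
        if pf.shape != pm.shape or pf.ndim != 2 or pf.shape[1] != 3:
            raise ValueError(
                f"landmark lists must both be (M, 3), got {pf.shape} and {pm.shape}"
            )
        if not (np.all(np.isfinite(pf)) and np.all(np.isfinite(pm))):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points_fixed", pf)
        object.__setattr__(self, "points_moving", pm)

    @property
    def m(self) -> int:
        return self.points_fixed.shape[0]


class TREResult(NamedTuple):
    """Per-landmark target registration errors (mm) and their mean.

    ``per_landmark`` holds NaN for landmarks outside the DVF extent
    (``outside`` marks them); the mean is over in-field landmarks only.
    """

    per_landmark: np.ndarray
    mean: float
    outside: np.ndarray


def image_mae(
    fixed: ScalarVolume,
    moved: ScalarVolume,
    mask: Optional[LabelMap] = None,
) -> float:
    """Mean absolute intensity error (HU) between fixed and deformed-moving.

    Computed over ``mask > 0`` if given, else the whole (shared) extent. The
    two volumes must already live on the same grid.
    """
    if fixed.shape != moved.shape or not fixed.geometry.close_to(moved.geometry):
        raise GridMismatchError(
            "fixed and moved volumes are on different grids; resample first"
        )
    diff = np.abs(fixed.data - moved.data)
    if mask is not None:
        if mask.shape != fixed.shape or not mask.geometry.close_to(fixed.geometry):
            raise GridMismatchError("mask is on a different grid than the images")
        sel = mask.labels > 0
        if not np.any(sel):
            raise ValueError("mask is empty")
        diff = diff[sel]
    return float(diff.mean())


def landmark_tre(dvf: VectorField, landmarks: LandmarkSet) -> TREResult:
    """Target registration error per landmark pair.

    Each fixed landmark is pushed through the DVF (trilinear interpolation)
    and compared with its moving partner:
    ``TRE_j = ||(x_f,j + d(x_f,j)) - x_m,j||`` in mm.
    """
    d, inside = dvf.sample(landmarks.points_fixed)
    mapped = landmarks.points_fixed + d
    tre = np.linalg.norm(mapped - landmarks.points_moving, axis=1)
    tre = np.where(inside, tre, np.nan)
    if not np.any(inside):
        raise ValueError("all landmarks fall outside the DVF extent")
    return TREResult(
        per_landmark=tre, mean=float(np.nanmean(tre)), outside=~inside
    )


def jacobian_determinant(dvf: VectorField) -> ScalarVolume:
    """det(I + ∇d) per voxel: local volume change of the transformation.

    Values > 1 indicate expansion, < 1 contraction, ≤ 0 folding. Gradients
    are taken in world units — central differences in the grid interior,
    one-sided at the borders, with the direction matrix applied so oblique
    grids are handled correctly. A rigid field scores exactly 1 everywhere
    (its displacement is linear in x, which finite differences reproduce).
    """
    if min(dvf.shape) < 3:
        raise FieldTooSmallError(
            f"need >= 3 voxels per axis for gradients, got shape {dvf.shape}"
        )
    geom = dvf.geometry
    # d(d_a)/d(u_k) with u the spacing-scaled index coordinate
    grad = np.empty(dvf.shape + (3, 3))
    for a in range(3):
        gk = np.gradient(dvf.data[..., a], *geom.spacing, axis=(0, 1, 2))
        for k in range(3):
            grad[..., a, k] = gk[k]
    # chain rule to world axes: x = origin + D u  =>  d/dx = (d/du) D^{-1}
    d_inv = np.linalg.inv(geom.direction)
    jac = np.einsum("...ak,kb->...ab", grad, d_inv)
    det = np.linalg.det(np.eye(3) + jac)
    return ScalarVolume(det, geom)


def bre_tre_correlation(bre_values, tre_values) -> float:
    """Pearson correlation between paired BRE and TRE values.

    Quantifies how far bone rigidity can stand in for landmark accuracy
    across registrations.
    """
    x = np.asarray(bre_values, dtype=float)
    y = np.asarray(tre_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)
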