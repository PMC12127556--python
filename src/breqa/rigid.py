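"""Per-bone rigid fitting and the bone rigidity error (BRE).

Bones do not deform. A deformable registration restricted to a single bone
should therefore be (close to) a rigid transform, even though neighbouring
bones may carry different rigid transforms. The BRE quantifies the violation:
for every voxel centre ``x_i`` inside one connected bone, the deformation
vector field (DVF) provides a displacement ``d_i`` and hence a deformed point
``y_i = x_i + d_i``. The least-squares rigid transform

    (R*, t*) = argmin_{R in SO(3), t}  sum_i || (R x_i + t) - y_i ||^2

is fitted to the point pairs, and the BRE is the mean residual distance

    BRE = (1/N) sum_i || (R* x_i + t*) - y_i ||      [mm].

A BRE of zero means the DVF moves the bone rigidly (which is necessary for
plausibility, not sufficient for correctness — a wrong but rigid motion also
scores zero). The rotation is obtained in closed form from the SVD of the
cross-covariance of the centred point sets (the Kabsch solution), with the
determinant correction that excludes improper rotations (reflections):

    H = sum_i (x_i - c_X)(y_i - c_Y)^T,   H = U S V^T
    R* = V diag(1, 1, det(V U^T)) U^T,    t* = c_Y - R* c_X.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .grids import Geometry, LabelMap, VectorField

__all__ = [
    "CorrespondenceSet",
    "RigidTransform",
    "BoneResult",
    "extract_correspondences",
    "fit_rigid",
    "compute_bre",
    "bone_bre",
    "split_connected_components",
    "LabelNotFoundError",
    "OutOfFieldError",
    "UnderdeterminedError",
    "InvalidPointsError",
]

#: bones with fewer voxels than this are flagged "too-small" and excluded
#: from averages — near-collinear point sets make the rotation ill-determined
DEFAULT_MIN_VOXELS = 10

#: bones with a larger fraction of voxels outside the DVF extent are flagged
#: "out-of-field"; smaller fractions are silently dropped from the sum
DEFAULT_MAX_OUTSIDE_FRACTION = 0.01

# flag states a BoneResult can carry
FLAG_UNSET = "unset"
FLAG_PASS = "pass"
FLAG_INSPECT = "inspect"
FLAG_TOO_SMALL = "too-small"
FLAG_OUT_OF_FIELD = "out-of-field"
FLAG_NO_THRESHOLD = "no-threshold"

#: flags that exclude a bone from group averages
EXCLUDED_FLAGS = frozenset({FLAG_TOO_SMALL, FLAG_OUT_OF_FIELD})


class LabelNotFoundError(KeyError):
    """Requested label is absent from the label map."""


class OutOfFieldError(ValueError):
    """Too large a fraction of a bone lies outside the DVF extent."""

    def __init__(self, label: int, fraction: float):
        self.label = label
        self.fraction = fraction
        super().__init__(
            f"label {label}: {fraction:.1%} of voxels fall outside the DVF extent"
        )


class UnderdeterminedError(ValueError):
    """Fewer than 3 correspondences: the rigid fit is underdetermined."""


class InvalidPointsError(ValueError):
    """Non-finite coordinates in a correspondence set."""


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired fixed-image points ``X`` and deformed points ``Y = X + D``.

    Both arrays are (N, 3) world coordinates in mm. ``Y - X`` recovers the
    sampled displacements.
    """

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                f"X and Y must both be (N, 3), got {X.shape} and {Y.shape}"
            )
        if X.shape[0] < 1:
            raise ValueError("at least one correspondence is required")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation ``R`` plus translation ``t`` (mm): x ↦ R x + t."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-9:
            raise ValueError("R is not orthogonal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("R is not a proper rotation (det != +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (..., 3) world points."""
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class BoneResult:
    """Per-bone outcome: voxel count, BRE (mm), fitted transform, flag state.

    ``bre`` and ``transform`` are ``None`` when the bone was excluded
    (``too-small`` or ``out-of-field``).
    """

    label: int
    n: int
    bre: Optional[float]
    transform: Optional[RigidTransform]
    name: Optional[str] = None
    group: Optional[str] = None
    flag: str = FLAG_UNSET
    threshold: Optional[float] = None

    @property
    def usable(self) -> bool:
        """True when the bone contributes to group averages."""
        return self.bre is not None and self.flag not in EXCLUDED_FLAGS

    def with_flag(self, flag: str, threshold: Optional[float] = None) -> "BoneResult":
        return replace(self, flag=flag, threshold=threshold)


def extract_correspondences(
    dvf: VectorField,
    labels: LabelMap,
    label: int,
    *,
    stride: int = 1,
    max_outside_fraction: float = DEFAULT_MAX_OUTSIDE_FRACTION,
) -> CorrespondenceSet:
    """Build the point pairs (x_i, y_i) for one bone.

    Correspondences are generated on the label-map (fixed-image) grid: each
    voxel centre carrying ``label`` becomes a fixed point ``x_i`` in world mm,
    and its displacement ``d_i`` is trilinearly interpolated from the DVF
    (an exact lookup when the grids coincide); ``y_i = x_i + d_i``.

    Parameters
    ----------
    stride : int
        Keep every ``stride``-th bone voxel (default 1 = every voxel).
    max_outside_fraction : float
        If more than this fraction of the bone's voxels fall outside the DVF
        extent, raise :class:`OutOfFieldError`; otherwise such voxels are
        silently dropped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = labels.voxel_indices(label)
    if idx.shape[0] == 0:
        raise LabelNotFoundError(f"label {label} not present in the label map")
    idx = idx[::stride]
    x = labels.geometry.world_from_index(idx)
    d, inside = dvf.sample(x)
    outside_fraction = 1.0 - float(np.mean(inside))
    if outside_fraction > max_outside_fraction:
        raise OutOfFieldError(label, outside_fraction)
    x, d = x[inside], d[inside]
    return CorrespondenceSet(X=x, Y=x + d)


def fit_rigid(corr: CorrespondenceSet) -> RigidTransform:
    """Least-squares proper-rigid fit mapping ``corr.X`` onto ``corr.Y``.

    Closed-form Kabsch/SVD solution of the constrained minimisation above.
    Degenerate (collinear/coplanar) point sets still return a minimiser;
    the residual value is then unique even though the rotation may not be.

    Raises
    ------
    UnderdeterminedError
        Fewer than 3 point pairs.
    InvalidPointsError
        Non-finite coordinates.
    """
    if corr.n < 3:
        raise UnderdeterminedError(
            f"need at least 3 correspondences for a rigid fit, got {corr.n}"
        )
    if not (np.all(np.isfinite(corr.X)) and np.all(np.isfinite(corr.Y))):
        raise InvalidPointsError("correspondence coordinates must be finite")

    c_x = corr.X.mean(axis=0)
    c_y = corr.Y.mean(axis=0)
    # cross-covariance H = sum_i (x_i - c_X)(y_i - c_Y)^T
    H = (corr.X - c_x).T @ (corr.Y - c_y)
    U, _, Vt = np.linalg.svd(H)
    V = Vt.T
    # determinant correction: flip the weakest singular direction rather than
    # accept a reflection
    d = np.sign(np.linalg.det(V @ U.T))
    R = V @ np.diag([1.0, 1.0, d]) @ U.T
    t = c_y - R @ c_x
    return RigidTransform(R, t)


def compute_bre(corr: CorrespondenceSet, transform: RigidTransform) -> float:
    """Mean residual distance (mm) of a rigid transform on a correspondence set.

    ``(1/N) sum_i ||(R x_i + t) - y_i||`` — the BRE when ``transform`` is the
    least-squares fit for ``corr``.
    """
    residuals = transform.apply(corr.X) - corr.Y
    return float(np.mean(np.linalg.norm(residuals, axis=1)))


def bone_bre(
    dvf: VectorField,
    labels: LabelMap,
    label: int,
    *,
    name: Optional[str] = None,
    group: Optional[str] = None,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    stride: int = 1,
    max_outside_fraction: float = DEFAULT_MAX_OUTSIDE_FRACTION,
) -> BoneResult:
    """Extract, fit and score one bone; convenience composition.

    Bones with fewer than ``min_voxels`` voxels are flagged ``too-small`` and
    bones with too many voxels outside the DVF extent ``out-of-field``; in
    both cases the BRE is omitted. Deterministic for fixed inputs.
    """
    n_total = int(np.count_nonzero(labels.labels == label))
    if n_total == 0:
        raise LabelNotFoundError(f"label {label} not present in the label map")
    if n_total < min_voxels:
        return BoneResult(
            label=label, n=n_total, bre=None, transform=None,
            name=name, group=group, flag=FLAG_TOO_SMALL,
        )
    try:
        corr = extract_correspondences(
            dvf, labels, label,
            stride=stride, max_outside_fraction=max_outside_fraction,
        )
    except OutOfFieldError:
        return BoneResult(
            label=label, n=n_total, bre=None, transform=None,
            name=name, group=group, flag=FLAG_OUT_OF_FIELD,
        )
    transform = fit_rigid(corr)
    bre = compute_bre(corr, transform)
    return BoneResult(
        label=label, n=corr.n, bre=bre, transform=transform,
        name=name, group=group,
    )


def split_connected_components(
    labels: LabelMap,
) -> tuple[LabelMap, dict[int, list[int]]]:
    """Split every label into its 26-connected components.

    A "bone" is a single connected piece of bone (one rib, one vertebra), so
    a label covering several disjoint pieces — e.g. a pooled "ribs" label —
    must be split before fitting, each piece receiving its own rigid fit.
    26-connectivity keeps thin oblique structures (ribs) in one piece.

    Returns the relabelled map (new labels numbered 1..K in order of the old
    labels) and a mapping ``old label -> [new labels]``.
    """
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    out = np.zeros_like(labels.labels, dtype=np.int32)
    mapping: dict[int, list[int]] = {}
    next_label = 1
    for old in labels.present_labels():
        components, n_comp = ndimage.label(labels.labels == old, structure=structure)
        new_labels = []
        for comp in range(1, n_comp + 1):
            out[components == comp] = next_label
            new_labels.append(next_label)
            next_label += 1
        mapping[old] = new_labels
    return LabelMap(out, labels.geometry), mapping
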