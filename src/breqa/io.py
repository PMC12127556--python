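"""File I/O: NIfTI / MHA volumes, landmark lists, YAML configs.

NIfTI (.nii/.nii.gz) goes through nibabel, MHA/MHD through SimpleITK. Headers
are taken at face value: all inputs of one run must share a single world
frame, and displacement components are interpreted as fixed→moving world-mm
vectors (ITK-convention fields already satisfy this in their own frame).
Arrays are held index-ordered (i, j, k) matching the image axes.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .grids import Geometry, LabelMap, ScalarVolume, VectorField

__all__ = [
    "read_vector_field",
    "write_vector_field",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_label_map",
    "write_label_map",
    "read_landmarks",
    "load_yaml",
    "dump_yaml",
    "FormatError",
]


class FormatError(ValueError):
    """A file could not be interpreted; the message names the file."""


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _is_mha(path: Path) -> bool:
    return path.suffix.lower() in (".mha", ".mhd")


def _geometry_from_affine(affine: np.ndarray) -> Geometry:
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    return Geometry(affine[:3, 3], spacing, direction)


def _read_nifti(path: Path) -> tuple[np.ndarray, Geometry]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), _geometry_from_affine(img.affine)


def _read_sitk(path: Path) -> tuple[np.ndarray, Geometry]:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x[, c])
    if arr.ndim == 3:
        arr = arr.transpose(2, 1, 0)
    elif arr.ndim == 4:
        arr = arr.transpose(2, 1, 0, 3)
    else:
        raise FormatError(f"{path}: unsupported dimensionality {arr.ndim}")
    geom = Geometry(
        np.asarray(img.GetOrigin()),
        np.asarray(img.GetSpacing()),
        np.asarray(img.GetDirection()).reshape(3, 3),
    )
    return arr, geom


def _read_any(path) -> tuple[np.ndarray, Geometry]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        if _is_nifti(path):
            return _read_nifti(path)
        if _is_mha(path):
            return _read_sitk(path)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise FormatError(f"{path}: could not read ({exc})") from exc
    raise FormatError(f"{path}: unsupported format (expect .nii/.nii.gz/.mha/.mhd)")


def read_vector_field(path) -> VectorField:
    """Read a DVF: 4D NIfTI (last axis = 3) or 3-component MHA vector image.

    NIfTI vector images stored as (nx, ny, nz, 1, 3) are squeezed.
    """
    arr, geom = _read_any(path)
    if arr.ndim == 5 and arr.shape[3] == 1:
        arr = arr[:, :, :, 0, :]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 3-component vector image, got shape {arr.shape}"
        )
    return VectorField(np.asarray(arr, dtype=float), geom)


def read_scalar_volume(path) -> ScalarVolume:
    arr, geom = _read_any(path)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar volume, got shape {arr.shape}")
    return ScalarVolume(np.asarray(arr, dtype=float), geom)


def read_label_map(path) -> LabelMap:
    arr, geom = _read_any(path)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D label map, got shape {arr.shape}")
    try:
        return LabelMap(arr, geom)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _write_nifti(arr: np.ndarray, geom: Geometry, path: Path) -> None:
    img = nib.Nifti1Image(arr, geom.affine)
    nib.save(img, str(path))


def _write_sitk(arr: np.ndarray, geom: Geometry, path: Path, vector: bool) -> None:
    if vector:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(arr.transpose(2, 1, 0, 3)), isVector=True
        )
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetOrigin(tuple(geom.origin))
    img.SetSpacing(tuple(geom.spacing))
    img.SetDirection(tuple(geom.direction.ravel()))
    sitk.WriteImage(img, str(path))


def write_vector_field(field: VectorField, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        _write_nifti(field.data, field.geometry, path)
    elif _is_mha(path):
        _write_sitk(field.data, field.geometry, path, vector=True)
    else:
        raise FormatError(f"{path}: unsupported output format")


def write_scalar_volume(volume: ScalarVolume, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        _write_nifti(volume.data, volume.geometry, path)
    elif _is_mha(path):
        _write_sitk(volume.data, volume.geometry, path, vector=False)
    else:
        raise FormatError(f"{path}: unsupported output format")


def write_label_map(labels: LabelMap, path) -> None:
    path = Path(path)
    arr = labels.labels.astype(np.int32)
    if _is_nifti(path):
        _write_nifti(arr, labels.geometry, path)
    elif _is_mha(path):
        _write_sitk(arr, labels.geometry, path, vector=False)
    else:
        raise FormatError(f"{path}: unsupported output format")


def read_landmarks(path, geometry: Geometry | None = None, coords: str = "world") -> np.ndarray:
    """Read an (M, 3) point list: one "x y z" (or comma-separated) per line.

    ``coords="index"`` converts voxel indices to world mm using ``geometry``.
    Covers common 4D-CT landmark list formats.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        pts = np.loadtxt(path, ndmin=2)
    except ValueError:
        try:
            pts = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: could not parse point list ({exc})") from exc
    if pts.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns, got {pts.shape[1]}")
    if coords == "index":
        if geometry is None:
            raise ValueError("index-coordinate landmarks need an image geometry")
        pts = geometry.world_from_index(pts)
    elif coords != "world":
        raise ValueError(f"unknown coordinate mode {coords!r}")
    return pts


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
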