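"""End-to-end runs: load inputs, score every bone, aggregate, write reports.

This is the layer the command line wraps; all logic is importable so the same
runs can be driven from Python. A run is deterministic: identical configs and
inputs produce byte-identical CSV/JSON reports (the creation timestamp lives
in a metadata field excluded from report equality).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as bio
from .grids import LabelMap, VectorField
from .metrics import LandmarkSet, image_mae, jacobian_determinant, landmark_tre
from .report import (
    QAReport,
    ThresholdTable,
    aggregate,
    flag_bones,
    render_report,
)
from .rigid import (
    DEFAULT_MAX_OUTSIDE_FRACTION,
    DEFAULT_MIN_VOXELS,
    bone_bre,
    split_connected_components,
)

__all__ = ["RunConfig", "run_bre", "run_metrics", "evaluate_bones"]

logger = logging.getLogger("breqa")

#: declared displacement-field convention, embedded in every report
DVF_CONVENTION = "fixed-to-moving displacement, world millimetres, y = x + d"


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs for one QA run; round-trips losslessly through YAML."""

    dvf: str
    labels: str
    out: str = "."
    fixed: Optional[str] = None
    moved: Optional[str] = None
    landmarks_fixed: Optional[str] = None
    landmarks_moving: Optional[str] = None
    landmark_coords: str = "world"
    groups: Optional[str] = None  # YAML label dictionary
    thresholds: Optional[str] = None  # YAML threshold table
    default_threshold: Optional[float] = None
    stride: int = 1
    min_voxels: int = DEFAULT_MIN_VOXELS
    max_outside_fraction: float = DEFAULT_MAX_OUTSIDE_FRACTION
    split_components: bool = True
    figures: str = "none"  # none | flagged | all

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**bio.load_yaml(path))

    def to_yaml(self, path) -> None:
        bio.dump_yaml(asdict(self), path)

    def hash(self) -> str:
        # the output directory does not influence the analysis
        payload = {k: v for k, v in asdict(self).items() if k != "out"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_label_dictionary(path) -> tuple[dict[int, dict], Optional[str]]:
    """YAML label dictionary: ``labels: {<int>: {name, group}}`` plus an
    optional ``default_group``."""
    data = bio.load_yaml(path)
    entries = {}
    for key, val in (data.get("labels") or {}).items():
        val = val or {}
        entries[int(key)] = {"name": val.get("name"), "group": val.get("group")}
    return entries, data.get("default_group")


def _load_threshold_table(path) -> tuple[ThresholdTable, Optional[float]]:
    data = bio.load_yaml(path)
    table = ThresholdTable(
        {str(g): float(v) for g, v in (data.get("thresholds") or {}).items()},
        multiplier=float(data.get("multiplier", 1.5)),
    )
    default = data.get("default_threshold")
    return table, None if default is None else float(default)


def evaluate_bones(
    dvf: VectorField,
    labels: LabelMap,
    *,
    label_info: Optional[dict[int, dict]] = None,
    default_group: Optional[str] = None,
    split_components: bool = True,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    stride: int = 1,
    max_outside_fraction: float = DEFAULT_MAX_OUTSIDE_FRACTION,
):
    """Score every bone in a label map; the in-memory core of a run.

    Labels are first split into 26-connected components (one fit per physical
    bone). Component bones inherit name and group from their original label;
    a label without a dictionary entry falls back to its own name as a
    singleton group, so ungrouped runs still aggregate sensibly.
    """
    label_info = label_info or {}
    if split_components:
        split, mapping = split_connected_components(labels)
    else:
        split = labels
        mapping = {lab: [lab] for lab in labels.present_labels()}

    bones = []
    for old, new_labels in mapping.items():
        info = label_info.get(old, {})
        base_name = info.get("name") or f"label_{old}"
        group = info.get("group") or default_group or base_name
        multi = len(new_labels) > 1
        for i, new in enumerate(new_labels, start=1):
            name = f"{base_name}#{i}" if multi else base_name
            t0 = time.perf_counter()
            bone = bone_bre(
                dvf, split, new,
                name=name, group=group,
                min_voxels=min_voxels, stride=stride,
                max_outside_fraction=max_outside_fraction,
            )
            logger.info(
                "bone %-24s label %3d  N=%6d  BRE=%s  [%.3f s]",
                name, new, bone.n,
                "   n/a" if bone.bre is None else f"{bone.bre:6.3f} mm",
                time.perf_counter() - t0,
            )
            bones.append(bone)
    return bones, split


def run_bre(config: RunConfig) -> QAReport:
    """Full BRE run from files: load, split, fit, aggregate, flag, write."""
    dvf = bio.read_vector_field(config.dvf)
    labels = bio.read_label_map(config.labels)

    label_info: dict[int, dict] = {}
    default_group = None
    if config.groups is not None:
        label_info, default_group = _load_label_dictionary(config.groups)

    thresholds = None
    default_threshold = config.default_threshold
    if config.thresholds is not None:
        thresholds, table_default = _load_threshold_table(config.thresholds)
        if default_threshold is None:
            default_threshold = table_default

    bones, split = evaluate_bones(
        dvf, labels,
        label_info=label_info,
        default_group=default_group,
        split_components=config.split_components,
        min_voxels=config.min_voxels,
        stride=config.stride,
        max_outside_fraction=config.max_outside_fraction,
    )
    bones = flag_bones(bones, thresholds, default_threshold=default_threshold)
    group_means, overall = aggregate(bones)

    from . import __version__

    report = QAReport(
        bones=bones,
        group_means=group_means,
        overall_mean=overall,
        metadata={
            "tool": f"breqa {__version__}",
            "dvf_convention": DVF_CONVENTION,
            "config_hash": config.hash(),
            "quantile_convention": "linear interpolation, Q3 + 1.5*IQR outliers",
            "min_voxels": config.min_voxels,
            "stride": config.stride,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    out_dir = Path(config.out)
    render_report(report, out_dir)
    if config.figures in ("flagged", "all"):
        from .report import plot_bone_vectors

        fig_dir = out_dir / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        for bone in bones:
            if bone.bre is None:
                continue
            if config.figures == "flagged" and bone.flag != "inspect":
                continue
            plot_bone_vectors(
                dvf, split, bone, fig_dir / f"bone_{bone.label:03d}.png"
            )
    return report


def run_metrics(config: RunConfig) -> dict:
    """Complementary metrics: MAE, TRE, Jacobian-determinant summary.

    Writes ``metrics.json`` next to the BRE report and returns its payload.
    """
    dvf = bio.read_vector_field(config.dvf)
    results: dict = {}

    if config.fixed is not None and config.moved is not None:
        fixed = bio.read_scalar_volume(config.fixed)
        moved = bio.read_scalar_volume(config.moved)
        results["mae_hu"] = image_mae(fixed, moved)

    if config.landmarks_fixed is not None and config.landmarks_moving is not None:
        pf = bio.read_landmarks(
            config.landmarks_fixed, dvf.geometry, config.landmark_coords
        )
        pm = bio.read_landmarks(
            config.landmarks_moving, dvf.geometry, config.landmark_coords
        )
        tre = landmark_tre(dvf, LandmarkSet(pf, pm))
        results["tre_mm"] = {
            "mean": tre.mean,
            "per_landmark": [
                None if np.isnan(v) else float(v) for v in tre.per_landmark
            ],
            "n_outside": int(tre.outside.sum()),
        }

    det = jacobian_determinant(dvf).data
    mask = None
    if config.labels is not None and Path(config.labels).exists():
        mask = bio.read_label_map(config.labels).labels > 0
        if not mask.any():
            mask = None
    region = det[mask] if mask is not None else det
    results["jacobian_determinant"] = {
        "min": float(det.min()),
        "fraction_nonpositive": float(np.mean(det <= 0)),
        "mean": float(region.mean()),
        "mean_region": "bone mask" if mask is not None else "whole field",
    }

    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
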