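"""Aggregation, inspection thresholds and QA report rendering.

Per-bone BREs are first averaged within anatomical groups (all ribs, left +
right hip, ...) and the overall score is the unweighted mean of the group
means, so that numerous small bones (ribs, vertebrae) do not drown out the
rest. Inspection thresholds follow the conventional boxplot outlier rule,
Q3 + 1.5·IQR, derived per group from reference registrations the user trusts;
bones whose BRE exceeds their group threshold are flagged for visual
inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .rigid import (
    FLAG_INSPECT,
    FLAG_NO_THRESHOLD,
    FLAG_PASS,
    BoneResult,
    RigidTransform,
)

__all__ = [
    "GroupConfig",
    "ThresholdTable",
    "QAReport",
    "aggregate",
    "derive_thresholds",
    "flag_bones",
    "render_report",
    "InsufficientReferenceError",
]

#: column order of the CSV report — stable across runs
CSV_COLUMNS = ["label", "name", "group", "n", "bre_mm", "threshold_mm", "flag"]


class InsufficientReferenceError(ValueError):
    """Too few reference BRE values to derive a threshold."""


@dataclass(frozen=True)
class GroupConfig:
    """Maps bones to anatomical groups, by name or by label.

    Lookup order: bone name, then label, then ``default_group`` (if set).
    """

    by_name: dict[str, str] = field(default_factory=dict)
    by_label: dict[int, str] = field(default_factory=dict)
    default_group: Optional[str] = None

    def group_of(self, bone: BoneResult) -> Optional[str]:
        if bone.name is not None and bone.name in self.by_name:
            return self.by_name[bone.name]
        if bone.label in self.by_label:
            return self.by_label[bone.label]
        return self.default_group

    def assign(self, bones: list[BoneResult]) -> list[BoneResult]:
        """Return bones with their ``group`` field filled in."""
        from dataclasses import replace

        return [replace(b, group=self.group_of(b)) for b in bones]


@dataclass(frozen=True)
class ThresholdTable:
    """Per-group inspection thresholds in mm (all > 0)."""

    per_group: dict[str, float]
    multiplier: float = 1.5
    quantile_convention: str = "linear"

    def __post_init__(self) -> None:
        for group, thr in self.per_group.items():
            if not thr > 0:
                raise ValueError(f"threshold for {group!r} must be > 0, got {thr}")

    def get(self, group: Optional[str]) -> Optional[float]:
        if group is None:
            return None
        return self.per_group.get(group)


def aggregate(
    bones: list[BoneResult],
) -> tuple[dict[str, float], float]:
    """Group means and their unweighted overall mean.

    Bones flagged ``too-small``/``out-of-field`` (no BRE) are excluded;
    a group left empty after exclusions is dropped. Each bone must carry
    its ``group`` (use :meth:`GroupConfig.assign` first).
    """
    per_group: dict[str, list[float]] = {}
    for bone in bones:
        if not bone.usable:
            continue
        if bone.group is None:
            raise ValueError(
                f"bone label {bone.label} has no group; assign groups before aggregating"
            )
        per_group.setdefault(bone.group, []).append(bone.bre)
    # sorted summation makes the result exactly permutation-invariant
    group_means = {g: float(np.mean(np.sort(v))) for g, v in sorted(per_group.items())}
    overall = (
        float(np.mean(np.sort(list(group_means.values()))))
        if group_means
        else float("nan")
    )
    return group_means, overall


def derive_thresholds(
    reference_bres: dict[str, list[float]],
    *,
    multiplier: float = 1.5,
    min_samples: int = 4,
) -> ThresholdTable:
    """Boxplot-outlier thresholds per group: Q3 + multiplier·IQR.

    Quartiles use the linear-interpolation convention between order
    statistics (recorded in the table, since boxplot conventions differ).
    ``reference_bres`` should come from registrations judged acceptable.
    """
    per_group = {}
    for group, values in reference_bres.items():
        values = np.asarray(values, dtype=float)
        if values.size < min_samples:
            raise InsufficientReferenceError(
                f"group {group!r}: need >= {min_samples} reference values, "
                f"got {values.size}"
            )
        q1, q3 = np.percentile(values, [25, 75], method="linear")
        per_group[group] = float(q3 + multiplier * (q3 - q1))
    return ThresholdTable(per_group, multiplier=multiplier)


def flag_bones(
    bones: list[BoneResult],
    thresholds: Optional[ThresholdTable],
    *,
    default_threshold: Optional[float] = None,
) -> list[BoneResult]:
    """Set pass/inspect flags from the threshold table.

    A bone is flagged ``inspect`` iff its BRE strictly exceeds its group
    threshold (a BRE exactly at the outlier limit passes). Prior
    ``too-small``/``out-of-field`` flags are preserved. A bone whose group
    has no threshold uses ``default_threshold``; with none it is flagged
    ``no-threshold``.
    """
    out = []
    for bone in bones:
        if not bone.usable:
            out.append(bone)
            continue
        thr = thresholds.get(bone.group) if thresholds is not None else None
        if thr is None:
            thr = default_threshold
        if thr is None:
            out.append(bone.with_flag(FLAG_NO_THRESHOLD))
        elif bone.bre > thr:
            out.append(bone.with_flag(FLAG_INSPECT, thr))
        else:
            out.append(bone.with_flag(FLAG_PASS, thr))
    return out


@dataclass(frozen=True)
class QAReport:
    """Complete per-registration QA outcome.

    ``overall_mean`` is the unweighted mean of ``group_means``. ``metadata``
    records the DVF sign convention, tool version, configuration hash and
    similar provenance; a ``created`` timestamp, if present, is excluded from
    equality so identical runs compare equal.
    """

    bones: list[BoneResult]
    group_means: dict[str, float]
    overall_mean: float
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": b.label,
                "name": b.name or "",
                "group": b.group or "",
                "n": b.n,
                "bre_mm": b.bre,
                "threshold_mm": b.threshold,
                "flag": b.flag,
            }
            for b in self.bones
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_dict(self) -> dict:
        def _bone(b: BoneResult) -> dict:
            return {
                "label": b.label,
                "name": b.name,
                "group": b.group,
                "n": b.n,
                "bre_mm": b.bre,
                "threshold_mm": b.threshold,
                "flag": b.flag,
                "rotation": None if b.transform is None else b.transform.R.tolist(),
                "translation_mm": None if b.transform is None else b.transform.t.tolist(),
            }

        return {
            "bones": [_bone(b) for b in self.bones],
            "group_means_mm": self.group_means,
            "overall_mean_mm": self.overall_mean,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "QAReport":
        bones = []
        for b in payload["bones"]:
            transform = None
            if b.get("rotation") is not None:
                transform = RigidTransform(
                    np.asarray(b["rotation"]), np.asarray(b["translation_mm"])
                )
            bones.append(
                BoneResult(
                    label=b["label"],
                    n=b["n"],
                    bre=b["bre_mm"],
                    transform=transform,
                    name=b.get("name"),
                    group=b.get("group"),
                    flag=b.get("flag", "unset"),
                    threshold=b.get("threshold_mm"),
                )
            )
        return cls(
            bones=bones,
            group_means=dict(payload["group_means_mm"]),
            overall_mean=payload["overall_mean_mm"],
            metadata=dict(payload.get("metadata", {})),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QAReport):
            return NotImplemented

        def strip(meta: dict) -> dict:
            return {k: v for k, v in meta.items() if k != "created"}

        a, b = self.to_dict(), other.to_dict()
        a["metadata"], b["metadata"] = strip(a["metadata"]), strip(b["metadata"])
        return json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


def render_report(report: QAReport, out_dir, formats=("csv", "json")) -> dict:
    """Write the report deterministically; returns {format: path}."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if "csv" in formats:
        path = out_dir / "bre_report.csv"
        report.to_frame().to_csv(path, index=False, float_format="%.6g")
        written["csv"] = path
    if "json" in formats:
        path = out_dir / "bre_report.json"
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["json"] = path
    return written


def plot_bone_vectors(
    dvf,
    labels,
    bone: BoneResult,
    path,
    *,
    max_arrows: int = 400,
) -> None:
    """Overlay figure: DVF vectors (red) vs fitted rigid vectors (cyan).

    Projects the bone's voxels onto the two world axes of largest extent and
    draws both vector sets, the visual that makes a non-zero BRE concrete.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .rigid import extract_correspondences

    corr = extract_correspondences(dvf, labels, bone.label, max_outside_fraction=1.0)
    X, Y = corr.X, corr.Y
    if X.shape[0] > max_arrows:
        step = X.shape[0] // max_arrows
        X, Y = X[::step], Y[::step]
    rigid_Y = bone.transform.apply(X) if bone.transform is not None else X
    # plot in the plane of the two largest-extent axes
    extents = np.ptp(X, axis=0)
    ax0, ax1 = np.argsort(extents)[-2:]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.quiver(
        X[:, ax0], X[:, ax1], (Y - X)[:, ax0], (Y - X)[:, ax1],
        angles="xy", scale_units="xy", scale=1, color="red", width=0.003,
        label="DVF",
    )
    ax.quiver(
        X[:, ax0], X[:, ax1], (rigid_Y - X)[:, ax0], (rigid_Y - X)[:, ax1],
        angles="xy", scale_units="xy", scale=1, color="cyan", width=0.003,
        label="least-squares rigid",
    )
    title = f"label {bone.label}" if bone.name is None else bone.name
    bre_txt = "n/a" if bone.bre is None else f"{bone.bre:.3f} mm"
    ax.set_title(f"{title}: BRE = {bre_txt}")
    ax.set_xlabel(f"world axis {ax0} [mm]")
    ax.set_ylabel(f"world axis {ax1} [mm]")
    ax.legend(loc="best")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
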