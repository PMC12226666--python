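"""Readers and writers for the toolkit's file formats.

Volumes (numbered rib segmentations, binary detection maps) are NIfTI,
with voxel spacing taken from the header. Detections, fused detections,
reference annotations and reports are tab-separated tables with a
header row — diffable plain text, one record per line. CWIS labels are
validated (case-insensitively) on read, and every validation error
names the offending line.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cwis import CATEGORIES, UNKNOWN, CWISLabel, normalize_label
from .evaluate import ReferenceFracture
from .fusion import Box3D, FusedDetection, FusionConfig, ScoredBox
from .ribs import MAX_RIB_LABEL, RibLabelMap, format_rib, parse_rib

__all__ = [
    "read_labelmap",
    "write_labelmap",
    "read_detections",
    "write_detections",
    "read_fused",
    "write_fused",
    "read_references",
    "write_references",
    "RunConfig",
]

_CORNER_COLS = ["x_min", "y_min", "z_min", "x_max", "y_max", "z_max"]


def read_labelmap(path: str | Path) -> RibLabelMap:
    """Load a numbered rib segmentation from NIfTI.

    The volume must be integer-valued (float encodings of integers are
    accepted and cast); spacing comes from the header. Labels outside
    1..24 trigger a warning naming them.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: rib label map must be integer-valued")
        data = np.round(data).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in spacing):
        raise ValueError(f"{path}: missing or invalid voxel spacing {spacing}")
    unknown = sorted(int(v) for v in np.unique(data) if v < 0 or v > MAX_RIB_LABEL)
    if unknown:
        warnings.warn(f"{path}: labels outside 0..{MAX_RIB_LABEL}: {unknown}")
    return RibLabelMap(grid=data.astype(np.int16), spacing=spacing)


def write_labelmap(ribs: RibLabelMap, path: str | Path) -> None:
    affine = np.diag(list(ribs.spacing) + [1.0])
    nib.save(nib.Nifti1Image(ribs.grid.astype(np.int16), affine), str(path))


def _line(i: int) -> str:
    # header occupies line 1; data row i (0-based) is file line i + 2
    return f"line {i + 2}"


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _parse_box(row: pd.Series, path, i: int) -> Box3D:
    mins = tuple(int(row[c]) for c in _CORNER_COLS[:3])
    maxs = tuple(int(row[c]) for c in _CORNER_COLS[3:])
    try:
        return Box3D(mins, maxs)
    except ValueError as e:
        raise ValueError(f"{path} {_line(i)}: {e}") from None


def read_detections(path: str | Path) -> list[ScoredBox]:
    """Read raw per-model detections from the tabular dialect.

    Columns: scan_id, model_id, category, label, score, x_min..z_max.
    Labels are normalized case-insensitively; scores outside [0, 1],
    unknown labels and malformed boxes raise errors naming the line.
    """
    df = _read_table(path, ["scan_id", "model_id", "category", "label", "score"] + _CORNER_COLS)
    out: list[ScoredBox] = []
    for i, row in df.iterrows():
        box = _parse_box(row, path, i)
        try:
            score = float(row["score"])
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score {score} outside [0, 1]")
            label = normalize_label(str(row["label"]), str(row["category"]).strip().lower())
        except ValueError as e:
            raise ValueError(f"{path} {_line(i)}: {e}") from None
        out.append(
            ScoredBox(
                box=box,
                score=score,
                label=label,
                category=str(row["category"]).strip().lower(),
                model_id=str(row["model_id"]),
                scan_id=str(row["scan_id"]),
            )
        )
    return out


def write_detections(dets: Sequence[ScoredBox], path: str | Path) -> None:
    rows = []
    for d in dets:
        rows.append(
            {
                "scan_id": d.scan_id,
                "model_id": d.model_id,
                "category": d.category,
                "label": d.label,
                "score": d.score,
                **dict(zip(_CORNER_COLS, d.box.min_corner + d.box.max_corner)),
            }
        )
    cols = ["scan_id", "model_id", "category", "label", "score"] + _CORNER_COLS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_fused(path: str | Path) -> list[FusedDetection]:
    """Read fused detections (CWIS triple + contributors [+ rib])."""
    req = ["scan_id", "score", "type", "displacement", "location", "contributors"] + _CORNER_COLS
    df = _read_table(path, req)
    out: list[FusedDetection] = []
    for i, row in df.iterrows():
        box = _parse_box(row, path, i)
        try:
            label = CWISLabel(
                **{c: normalize_label(str(row[c]), c, allow_unknown=True) for c in CATEGORIES}
            )
            score = float(row["score"])
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score {score} outside [0, 1]")
            rib = parse_rib(row["rib"]) if "rib" in df.columns and not pd.isna(row["rib"]) else None
        except ValueError as e:
            raise ValueError(f"{path} {_line(i)}: {e}") from None
        source_scores = {
            c: float(row[f"{c}_score"])
            for c in CATEGORIES
            if f"{c}_score" in df.columns and not pd.isna(row[f"{c}_score"])
        }
        out.append(
            FusedDetection(
                box=box,
                label=label,
                score=score,
                contributors=tuple(str(row["contributors"]).split(";")),
                source_scores=source_scores,
                scan_id=str(row["scan_id"]),
                rib=rib,
            )
        )
    return out


def write_fused(dets: Sequence[FusedDetection], path: str | Path) -> None:
    rows = []
    for d in dets:
        rows.append(
            {
                "scan_id": d.scan_id,
                **dict(zip(_CORNER_COLS, d.box.min_corner + d.box.max_corner)),
                "score": d.score,
                **d.label.as_dict(),
                "contributors": ";".join(d.contributors),
                **{f"{c}_score": d.source_scores.get(c) for c in CATEGORIES},
                "rib": format_rib(d.rib) if d.rib is not None else "",
            }
        )
    cols = (
        ["scan_id"]
        + _CORNER_COLS
        + ["score"]
        + list(CATEGORIES)
        + ["contributors"]
        + [f"{c}_score" for c in CATEGORIES]
        + ["rib"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_references(path: str | Path) -> list[ReferenceFracture]:
    """Read reference fracture annotations.

    Columns: scan_id, x, y, z (center voxel coordinates), radius_mm,
    type, displacement, location, rib (e.g. 'L5'; empty allowed).
    """
    df = _read_table(path, ["scan_id", "x", "y", "z", "radius_mm"] + list(CATEGORIES))
    out: list[ReferenceFracture] = []
    for i, row in df.iterrows():
        try:
            label = CWISLabel(**{c: normalize_label(str(row[c]), c) for c in CATEGORIES})
            rib = parse_rib(row["rib"]) if "rib" in df.columns and not pd.isna(row["rib"]) else None
            out.append(
                ReferenceFracture(
                    center=(float(row["x"]), float(row["y"]), float(row["z"])),
                    label=label,
                    rib=rib,
                    radius_mm=float(row["radius_mm"]),
                    scan_id=str(row["scan_id"]),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} {_line(i)}: {e}") from None
    return out


def write_references(refs: Sequence[ReferenceFracture], path: str | Path) -> None:
    rows = []
    for r in refs:
        rows.append(
            {
                "scan_id": r.scan_id,
                "x": r.center[0],
                "y": r.center[1],
                "z": r.center[2],
                "radius_mm": r.radius_mm,
                **r.label.as_dict(),
                "rib": format_rib(r.rib) if r.rib is not None else "",
            }
        )
    cols = ["scan_id", "x", "y", "z", "radius_mm"] + list(CATEGORIES) + ["rib"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    detections: str = ""
    references: str = ""
    labelmap: str = ""
    output_dir: str = "."
    fusion: FusionConfig = field(default_factory=FusionConfig)
    target_sensitivity: float | None = None
    score_threshold: float | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        fusion = FusionConfig(**d.pop("fusion", {}))
        return cls(fusion=fusion, **d)
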