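"""Rib-number assignment from numbered rib segmentations.

A rib label map is an integer volume where 0 is background and labels
1–24 number the ribs: 1–12 are left ribs 1–12 (cranial to caudal),
13–24 the right ribs 1–12. Each fused detection is assigned the rib its
box overlaps most; boxes that do not overlap any rib are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .fusion import Box3D, FusedDetection

__all__ = [
    "RibLabelMap",
    "RibAssignment",
    "rib_side",
    "rib_number",
    "format_rib",
    "parse_rib",
    "boxes_to_labelmap",
    "assign_rib_numbers",
    "attach_ribs",
    "validate_rib_labelmap",
]

MAX_RIB_LABEL = 24


def rib_side(label: int) -> str:
    """'left' for labels 1-12, 'right' for 13-24."""
    if not 1 <= label <= MAX_RIB_LABEL:
        raise ValueError(f"rib label must be 1..{MAX_RIB_LABEL}, got {label}")
    return "left" if label <= 12 else "right"


def rib_number(label: int) -> int:
    """Anatomical rib number 1-12 of a 1-24 rib label."""
    if not 1 <= label <= MAX_RIB_LABEL:
        raise ValueError(f"rib label must be 1..{MAX_RIB_LABEL}, got {label}")
    return (label - 1) % 12 + 1


def format_rib(label: int | None) -> str:
    """Human-readable rib id, e.g. 5 -> 'L5', 17 -> 'R5'; None -> 'discarded'."""
    if label is None:
        return "discarded"
    return ("L" if rib_side(label) == "left" else "R") + str(rib_number(label))


def parse_rib(text: str) -> int | None:
    """Inverse of :func:`format_rib`."""
    t = str(text).strip().upper()
    if t in ("", "DISCARDED", "NONE", "NAN"):
        return None
    side, num = t[0], int(t[1:])
    if side not in ("L", "R") or not 1 <= num <= 12:
        raise ValueError(f"cannot parse rib id {text!r}")
    return num if side == "L" else num + 12


@dataclass
class RibLabelMap:
    """Numbered rib segmentation: integer grid + per-axis voxel spacing (mm)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("rib label map must be a 3D volume")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("rib label map must hold integer labels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive voxel sizes, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.grid) if v != 0)


@dataclass
class RibAssignment:
    """Outcome of rib assignment for one detection.

    ``rib`` is the winning 1-24 rib label, or None when the box overlaps
    no rib voxel at all (the detection is discarded). ``overlap_voxels``
    holds the per-rib overlap counts inside the box.
    """

    detection: FusedDetection
    rib: int | None
    overlap_voxels: dict[int, int] = field(default_factory=dict)

    @property
    def discarded(self) -> bool:
        return self.rib is None


def _clip_box(box: Box3D, shape: Sequence[int]) -> Box3D | None:
    mins = tuple(max(0, lo) for lo in box.min_corner)
    maxs = tuple(min(int(s), hi) for s, hi in zip(shape, box.max_corner))
    if any(hi <= lo for lo, hi in zip(mins, maxs)):
        return None
    return Box3D(mins, maxs)


def boxes_to_labelmap(dets: Sequence[FusedDetection], shape: Sequence[int]) -> np.ndarray:
    """Rasterize detection boxes into a binary volume (1 = inside >=1 box).

    Boxes reaching past the grid are clipped with a warning; boxes fully
    outside are ignored with a warning.
    """
    out = np.zeros(tuple(int(s) for s in shape), dtype=np.uint8)
    for det in dets:
        clipped = _clip_box(det.box, shape)
        if clipped is None:
            warnings.warn(f"detection box {det.box} lies entirely outside grid {tuple(shape)}; ignored")
            continue
        if clipped != det.box:
            warnings.warn(f"detection box {det.box} clipped to grid {tuple(shape)}")
        sl = tuple(slice(lo, hi) for lo, hi in zip(clipped.min_corner, clipped.max_corner))
        out[sl] = 1
    return out


def assign_rib_numbers(
    dets: Sequence[FusedDetection], ribs: RibLabelMap
) -> list[RibAssignment]:
    """Assign each detection the rib whose voxels its box overlaps most.

    Ties are broken toward the lower anatomical rib number, then left
    before right. A detection whose box overlaps only background is
    discarded (``rib=None``). Detections and rib map must share a grid.
    """
    assignments: list[RibAssignment] = []
    for det in dets:
        clipped = _clip_box(det.box, ribs.shape)
        if clipped is None:
            warnings.warn(f"detection box {det.box} lies outside the rib map; discarded")
            assignments.append(RibAssignment(det, None, {}))
            continue
        sl = tuple(slice(lo, hi) for lo, hi in zip(clipped.min_corner, clipped.max_corner))
        sub = ribs.grid[sl]
        counts = np.bincount(sub.ravel(), minlength=MAX_RIB_LABEL + 1)
        overlap = {int(lab): int(counts[lab]) for lab in range(1, MAX_RIB_LABEL + 1) if counts[lab] > 0}
        if not overlap:
            assignments.append(RibAssignment(det, None, {}))
            continue
        best_count = max(overlap.values())
        tied = [lab for lab, n in overlap.items() if n == best_count]
        # ties: lower anatomical rib number first, then left before right
        winner = min(tied, key=lambda lab: (rib_number(lab), rib_side(lab) != "left"))
        assignments.append(RibAssignment(det, winner, overlap))
    return assignments


def attach_ribs(dets: Sequence[FusedDetection], ribs: RibLabelMap) -> list[FusedDetection]:
    """Convenience: run :func:`assign_rib_numbers` and return detections
    with ``rib`` filled; discarded detections are dropped."""
    out = []
    for a in assign_rib_numbers(dets, ribs):
        if not a.discarded:
            out.append(a.detection.with_rib(a.rib))
    return out


@dataclass
class RibMapValidation:
    """Structural report on a numbered rib segmentation."""

    per_label: pd.DataFrame  # columns: label, rib, side, n_voxels, n_components
    flags: list[str]
    short_cage: bool

    @property
    def ok(self) -> bool:
        return not self.flags


_FULL_CONN = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def validate_rib_labelmap(ribs: RibLabelMap, expect_pairs: int | None = None) -> RibMapValidation:
    """Check a rib label map against the structural quality criteria:
    every expected rib number present (per side), each label forming a
    single rib (1 connected component; 2 tolerated for a fractured rib
    whose fragments correctly share the label), no stray labels.

    An 11-pair cage (ribs 12 absent on both sides) is a legitimate
    anatomical variant: it raises an informational ``short cage`` flag
    rather than missing-label errors.
    """
    rows = []
    flags: list[str] = []
    present = set(ribs.labels_present())
    stray = sorted(lab for lab in present if lab > MAX_RIB_LABEL)
    if stray:
        flags.append(f"labels outside 1..{MAX_RIB_LABEL}: {stray}")
        present -= set(stray)

    left = {rib_number(lab) for lab in present if rib_side(lab) == "left"}
    right = {rib_number(lab) for lab in present if rib_side(lab) == "right"}
    short_cage = left == set(range(1, 12)) and right == set(range(1, 12))
    if short_cage:
        flags.append("short cage: 11 rib pairs (rib 12 absent bilaterally)")
    else:
        expected = set(range(1, (expect_pairs or 12) + 1))
        for side, nums in (("left", left), ("right", right)):
            missing = sorted(expected - nums)
            if missing:
                flags.append(f"{side} ribs missing labels: {missing}")

    for lab in sorted(present):
        mask = ribs.grid == lab
        _, n_comp = ndimage.label(mask, structure=_FULL_CONN)
        rows.append(
            {
                "label": lab,
                "rib": format_rib(lab),
                "side": rib_side(lab),
                "n_voxels": int(mask.sum()),
                "n_components": int(n_comp),
            }
        )
        if n_comp > 2:
            flags.append(f"rib {format_rib(lab)} has {n_comp} fragments (more than 2)")
    per_label = pd.DataFrame(rows, columns=["label", "rib", "side", "n_voxels", "n_components"])
    return RibMapValidation(per_label=per_label, flags=flags, short_cage=short_cage)
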