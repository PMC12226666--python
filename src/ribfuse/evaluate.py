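"""Matching of detections to reference fractures and all derived metrics.

Ground-truth fractures are encoded as spheres of physical radius 10 mm
centered on the fracture; a fused detection may match a reference iff
its box intersects the reference sphere (anisotropic voxel spacing is
honoured by testing the box's closest point against per-axis voxel
radii). Matching is one-to-one with the maximum possible number of true
positives; among optimal matchings higher-scoring detections are
preferred, with center distance as tie-break, so a fracture detected
twice yields one true positive (the higher score) and one false
positive.

Metrics follow the standard detection conventions: pooled sensitivity
TP/(TP+FN), precision TP/(TP+FP), F1 as their harmonic mean, and FPPS
(false positives per scan) as total FP divided by the number of scans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cwis import CATEGORIES, UNKNOWN, VOCABULARY, CWISLabel
from .fusion import Box3D, FusedDetection

__all__ = [
    "ReferenceFracture",
    "MatchResult",
    "DetectionMetrics",
    "box_intersects_sphere",
    "match_detections",
    "detection_metrics",
    "per_class_metrics",
    "confusion_matrices",
    "rib_number_accuracy",
    "choose_operating_point",
    "stratified_metrics",
]


@dataclass(frozen=True)
class ReferenceFracture:
    """A ground-truth fracture: center point + 10 mm sphere + CWIS triple."""

    center: tuple[float, float, float]  # voxel coordinates
    label: CWISLabel
    rib: int | None = None
    radius_mm: float = 10.0
    scan_id: str | None = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("reference sphere radius must be positive")
        if not self.label.is_complete:
            raise ValueError("reference labels must be complete (no 'unknown')")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def box_intersects_sphere(
    box: Box3D,
    center: Sequence[float],
    radius_mm: float,
    spacing: Sequence[float],
) -> bool:
    """True iff the half-open voxel box intersects the physical sphere.

    The closest point of the box to the sphere center is found by
    clamping, then compared against the per-axis voxel radii
    ``radius_mm / spacing`` (an ellipsoid in voxel space).
    """
    q = 0.0
    for lo, hi, c, s in zip(box.min_corner, box.max_corner, center, spacing):
        p = min(max(c, lo), hi)
        q += ((c - p) * s) ** 2
    return q <= radius_mm**2


def _center_distance_mm(box: Box3D, center: Sequence[float], spacing: Sequence[float]) -> float:
    return math.sqrt(
        sum(((b - c) * s) ** 2 for b, c, s in zip(box.center, center, spacing))
    )


@dataclass
class MatchResult:
    """TP/FP/FN decomposition for one scan."""

    scan_id: str | None
    tp_pairs: list[tuple[FusedDetection, ReferenceFracture]]
    fp_detections: list[FusedDetection]
    fn_references: list[ReferenceFracture]

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_fp(self) -> int:
        return len(self.fp_detections)

    @property
    def n_fn(self) -> int:
        return len(self.fn_references)


def match_detections(
    dets: Sequence[FusedDetection],
    refs: Sequence[ReferenceFracture],
    spacing: Sequence[float],
) -> MatchResult:
    """One-to-one matching of detections to reference spheres.

    Among all one-to-one matchings restricted to feasible pairs (box
    intersects sphere), a matching with the maximum number of true
    positives is chosen; within that, higher-scoring detections are
    preferred as the matched ones, with center distance as the final
    tie-break (so of two detections on one fracture the higher-scoring
    becomes the TP and the other a FP). Solved with the Hungarian
    algorithm on a feasibility-dominated reward; deterministic.
    """
    scan_ids = {r.scan_id for r in refs if r.scan_id is not None}
    scan_ids |= {d.scan_id for d in dets if d.scan_id is not None}
    if len(scan_ids) > 1:
        raise ValueError(f"match_detections expects a single scan, got scan_ids {sorted(scan_ids)}")
    scan_id = scan_ids.pop() if scan_ids else None

    tp_pairs: list[tuple[FusedDetection, ReferenceFracture]] = []
    matched_d: set[int] = set()
    matched_r: set[int] = set()
    if dets and refs:
        from scipy.optimize import linear_sum_assignment

        feas = np.zeros((len(dets), len(refs)), dtype=bool)
        dist = np.zeros((len(dets), len(refs)))
        for i, d in enumerate(dets):
            for j, r in enumerate(refs):
                feas[i, j] = box_intersects_sphere(d.box, r.center, r.radius_mm, spacing)
                dist[i, j] = _center_distance_mm(d.box, r.center, spacing)
        # reward: 1 per matched pair dominates; small score / distance
        # perturbations order the optimal matchings
        n = min(len(dets), len(refs))
        eps_s = 0.5 / (n + 1)
        eps_d = eps_s / (2 * (n + 1) * (dist.max() + 1.0))
        scores = np.array([d.score for d in dets])
        reward = feas * (1.0 + eps_s * scores[:, None] - eps_d * dist)
        rows, cols = linear_sum_assignment(reward, maximize=True)
        order = np.argsort(-scores[rows], kind="stable")
        for i, j in zip(rows[order], cols[order]):
            if feas[i, j]:
                tp_pairs.append((dets[i], refs[j]))
                matched_d.add(i)
                matched_r.add(j)
    fp = [d for i, d in enumerate(dets) if i not in matched_d]
    fn = [r for j, r in enumerate(refs) if j not in matched_r]
    result = MatchResult(scan_id, tp_pairs, fp, fn)
    assert result.n_tp + result.n_fn == len(refs)
    assert result.n_tp + result.n_fp == len(dets)
    return result


@dataclass(frozen=True)
class DetectionMetrics:
    """Pooled detection counts and the metrics derived from them."""

    tp: int
    fp: int
    fn: int
    n_scans: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return None if d == 0 else self.tp / d

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return None if d == 0 else self.tp / d

    @property
    def f1(self) -> float | None:
        s, p = self.sensitivity, self.precision
        if s is None or p is None or s + p == 0:
            return None
        return 2 * s * p / (s + p)

    @property
    def fpps(self) -> float:
        return self.fp / self.n_scans

    def summary(self) -> dict[str, float | int | None]:
        """Presentation-rounded metrics: percentages to whole percent,
        FPPS to two decimals."""

        def pct(x: float | None) -> float | None:
            return None if x is None else round(100 * x)

        return {
            "sensitivity_pct": pct(self.sensitivity),
            "precision_pct": pct(self.precision),
            "f1_pct": pct(self.f1),
            "fpps": round(self.fpps, 2),
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "n_scans": self.n_scans,
        }


def detection_metrics(matches: Sequence[MatchResult]) -> DetectionMetrics:
    """Pool TP/FP/FN counts over scans into one set of metrics."""
    if not matches:
        raise ValueError("detection_metrics requires at least one scan")
    tp = sum(m.n_tp for m in matches)
    fp = sum(m.n_fp for m in matches)
    fn = sum(m.n_fn for m in matches)
    if tp + fn == 0:
        warnings.warn("no reference fractures: sensitivity is undefined")
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, n_scans=len(matches))


def macro_sensitivity(matches: Sequence[MatchResult]) -> float | None:
    """Per-scan-averaged sensitivity, exposed as an alternative to the
    pooled default (scans without references are skipped)."""
    sens = [m.n_tp / (m.n_tp + m.n_fn) for m in matches if m.n_tp + m.n_fn > 0]
    return float(np.mean(sens)) if sens else None


def per_class_metrics(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Detection sensitivity/precision per CWIS category value, plus the
    composition of missed fractures.

    Per value v of a category: sensitivity = TP among references labeled
    v over all references labeled v; precision = TP detections predicted
    v over all detections predicted v; ``fn_share`` = fraction of all
    missed fractures labeled v. Values absent from both references and
    predictions yield NaN entries.
    """
    rows = []
    all_fn = [r for m in matches for r in m.fn_references]
    for cat in CATEGORIES:
        for value in VOCABULARY[cat]:
            n_refs = sum(
                1
                for m in matches
                for r in [p[1] for p in m.tp_pairs] + m.fn_references
                if r.label[cat] == value
            )
            tp_refs = sum(1 for m in matches for _, r in m.tp_pairs if r.label[cat] == value)
            n_pred = sum(
                1
                for m in matches
                for d in [p[0] for p in m.tp_pairs] + m.fp_detections
                if d.label[cat] == value
            )
            tp_pred = sum(1 for m in matches for d, _ in m.tp_pairs if d.label[cat] == value)
            rows.append(
                {
                    "category": cat,
                    "value": value,
                    "n_refs": n_refs,
                    "sensitivity": tp_refs / n_refs if n_refs else float("nan"),
                    "precision": tp_pred / n_pred if n_pred else float("nan"),
                    "fn_share": (
                        sum(1 for r in all_fn if r.label[cat] == value) / len(all_fn)
                        if all_fn
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def confusion_matrices(matches: Sequence[MatchResult]) -> dict[str, pd.DataFrame]:
    """Per-category confusion matrices over true-positive pairs only
    (a missed fracture cannot be classified). Rows are reference labels,
    columns predicted labels plus ``unknown``."""
    out: dict[str, pd.DataFrame] = {}
    for cat in CATEGORIES:
        ref_vals = list(VOCABULARY[cat])
        pred_vals = list(VOCABULARY[cat]) + [UNKNOWN]
        mat = pd.DataFrame(0, index=ref_vals, columns=pred_vals, dtype=int)
        for m in matches:
            for det, ref in m.tp_pairs:
                mat.loc[ref.label[cat], det.label[cat]] += 1
        mat.index.name = "reference"
        mat.columns.name = "predicted"
        out[cat] = mat
    return out


def rib_number_accuracy(matches: Sequence[MatchResult]) -> float | None:
    """Fraction of true-positive detections carrying the correct rib.

    Only TP pairs where both the detection's assigned rib and the
    reference rib are known enter the denominator (discarded or
    unassigned detections are excluded). None when no such pair exists.
    """
    pairs = [
        (det, ref)
        for m in matches
        for det, ref in m.tp_pairs
        if det.rib is not None and ref.rib is not None
    ]
    if not pairs:
        return None
    return sum(det.rib == ref.rib for det, ref in pairs) / len(pairs)


def choose_operating_point(
    dets_by_scan: Mapping[str, Sequence[FusedDetection]],
    refs_by_scan: Mapping[str, Sequence[ReferenceFracture]],
    spacing: Sequence[float],
    target_sensitivity: float,
) -> float:
    """Largest score threshold whose pooled sensitivity meets the target.

    Sweeps candidate thresholds (the distinct detection scores) from
    high to low; sensitivity is non-increasing in the threshold, so the
    first threshold reaching the target is the largest. If even keeping
    every detection falls short, returns min score minus a small epsilon
    with a warning.
    """
    if not 0 < target_sensitivity <= 1:
        raise ValueError("target sensitivity must lie in (0, 1]")
    all_scores = sorted({d.score for dets in dets_by_scan.values() for d in dets}, reverse=True)
    if not all_scores:
        raise ValueError("no detections: cannot choose an operating point")

    def sensitivity_at(t: float) -> float:
        matches = [
            match_detections([d for d in dets_by_scan.get(s, []) if d.score >= t], refs, spacing)
            for s, refs in refs_by_scan.items()
        ]
        sens = detection_metrics(matches).sensitivity
        return 0.0 if sens is None else sens

    for t in all_scores:
        if sensitivity_at(t) >= target_sensitivity:
            return t
    warnings.warn(
        f"target sensitivity {target_sensitivity:.2f} unattainable even with every detection kept"
    )
    return all_scores[-1] - 1e-9


def stratified_metrics(
    matches: Sequence[MatchResult], scan_groups: Mapping[str, str]
) -> dict[str, DetectionMetrics]:
    """Detection metrics within groups of scans (e.g. slice-spacing strata).

    ``scan_groups`` maps scan_id to a group name and must cover every
    scan present in ``matches``. Groups without scans are simply absent
    from the result.
    """
    by_group: dict[str, list[MatchResult]] = {}
    for m in matches:
        if m.scan_id not in scan_groups:
            raise KeyError(f"scan {m.scan_id!r} missing from the grouping")
        by_group.setdefault(scan_groups[m.scan_id], []).append(m)
    return {g: detection_metrics(ms) for g, ms in sorted(by_group.items())}
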