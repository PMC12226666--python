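"""3D box geometry and ensemble fusion of category-specific detections.

One detector is trained per CWIS category (type / displacement /
location), so a single fracture can surface as up to three boxes, each
carrying one label. Fusion turns those per-model outputs into single
detections with a full CWIS triple:

1. within each model, greedy non-maximum suppression removes duplicate
   boxes (keep the highest score; suppress boxes whose IoU with a kept
   box exceeds a threshold, 0.5 by default);
2. boxes from different models that overlap are grouped (connected
   components of the cross-model overlap graph); groups supported by
   fewer than two models are discarded;
3. each surviving group is merged through the union (smallest enclosing
   box) of the best box per model; a category whose model is absent
   from the group is labeled ``"unknown"``.

All geometry is in 0-based voxel indices with half-open boxes
``[min_corner, max_corner)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .cwis import CATEGORIES, UNKNOWN, CWISLabel, normalize_label

__all__ = [
    "Box3D",
    "ScoredBox",
    "FusedDetection",
    "FusionConfig",
    "iou",
    "dedup_within_model",
    "fuse_models",
]


@dataclass(frozen=True, order=True)
class Box3D:
    """Axis-aligned 3D box on a voxel grid, half-open per axis."""

    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]

    def __post_init__(self) -> None:
        mins = tuple(int(v) for v in self.min_corner)
        maxs = tuple(int(v) for v in self.max_corner)
        object.__setattr__(self, "min_corner", mins)
        object.__setattr__(self, "max_corner", maxs)
        if len(mins) != 3 or len(maxs) != 3:
            raise ValueError("Box3D corners must be length-3 index triples")
        if any(hi <= lo for lo, hi in zip(mins, maxs)):
            raise ValueError(f"degenerate box: min_corner={mins} max_corner={maxs}")

    @property
    def volume(self) -> int:
        v = 1
        for lo, hi in zip(self.min_corner, self.max_corner):
            v *= hi - lo
        return v

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((lo + hi) / 2.0 for lo, hi in zip(self.min_corner, self.max_corner))

    def intersection_volume(self, other: "Box3D") -> int:
        v = 1
        for lo1, hi1, lo2, hi2 in zip(
            self.min_corner, self.max_corner, other.min_corner, other.max_corner
        ):
            w = min(hi1, hi2) - max(lo1, lo2)
            if w <= 0:
                return 0
            v *= w
        return v

    def union_with(self, other: "Box3D") -> "Box3D":
        """Smallest axis-aligned box containing both boxes."""
        return Box3D(
            tuple(min(a, b) for a, b in zip(self.min_corner, other.min_corner)),
            tuple(max(a, b) for a, b in zip(self.max_corner, other.max_corner)),
        )

    def contains_box(self, other: "Box3D") -> bool:
        return all(a <= b for a, b in zip(self.min_corner, other.min_corner)) and all(
            a >= b for a, b in zip(self.max_corner, other.max_corner)
        )


def iou(a: Box3D, b: Box3D) -> float:
    """Intersection-over-union of two half-open voxel boxes, in [0, 1]."""
    inter = a.intersection_volume(b)
    if inter == 0:
        return 0.0
    return inter / (a.volume + b.volume - inter)


@dataclass(frozen=True)
class ScoredBox:
    """One raw detection from one category model: box + score + label."""

    box: Box3D
    score: float
    label: str
    category: str
    model_id: str
    scan_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        object.__setattr__(self, "label", normalize_label(self.label, self.category))


@dataclass(frozen=True)
class FusedDetection:
    """An ensemble detection: union box, full CWIS triple, contributors.

    ``source_scores`` maps each contributing category to the score of its
    representative box; ``rib`` is filled by rib assignment (1–24 label,
    or ``None`` when unassigned/discarded).
    """

    box: Box3D
    label: CWISLabel
    score: float
    contributors: tuple[str, ...]
    source_scores: dict[str, float] = field(default_factory=dict)
    scan_id: str | None = None
    rib: int | None = None

    def __post_init__(self) -> None:
        if len(self.contributors) < 2:
            raise ValueError("a fused detection requires at least two contributing models")

    def with_rib(self, rib: int | None) -> "FusedDetection":
        return replace(self, rib=rib)


@dataclass
class FusionConfig:
    """Knobs of the ensemble fusion step.

    dedup_iou_threshold
        Within-model NMS: a box is suppressed when its IoU with an
        already-kept box exceeds this fraction (default 0.5).
    cross_model_overlap_rule
        When two boxes from different models count as overlapping:
        ``"positive-intersection"`` (any shared voxel, default) or
        ``"iou-threshold"`` (IoU above ``cross_model_iou_threshold``).
    score_aggregation
        Fused score: ``"mean"`` (default) or ``"max"`` over the
        representatives' scores.
    """

    dedup_iou_threshold: float = 0.5
    cross_model_overlap_rule: Literal["positive-intersection", "iou-threshold"] = (
        "positive-intersection"
    )
    cross_model_iou_threshold: float = 0.5
    score_aggregation: Literal["mean", "max"] = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.dedup_iou_threshold < 1.0:
            raise ValueError("dedup_iou_threshold must lie in (0, 1)")
        if self.cross_model_overlap_rule not in ("positive-intersection", "iou-threshold"):
            raise ValueError(f"unknown overlap rule {self.cross_model_overlap_rule!r}")
        if self.score_aggregation not in ("mean", "max"):
            raise ValueError(f"unknown score aggregation {self.score_aggregation!r}")


def _sort_key(d: ScoredBox) -> tuple:
    # score descending; ties broken by lexicographic corners for determinism
    return (-d.score, d.box.min_corner, d.box.max_corner)


def dedup_within_model(dets: Sequence[ScoredBox], cfg: FusionConfig | None = None) -> list[ScoredBox]:
    """Greedy NMS over one model's detections.

    Boxes are visited by descending score; a box is kept iff its IoU with
    every already-kept box is at most ``cfg.dedup_iou_threshold``. All
    detections must share one ``model_id`` and category.
    """
    cfg = cfg or FusionConfig()
    dets = list(dets)
    if not dets:
        return []
    model_ids = {d.model_id for d in dets}
    categories = {d.category for d in dets}
    if len(model_ids) > 1 or len(categories) > 1:
        raise ValueError(
            f"dedup_within_model expects one model and category, got models={sorted(model_ids)} "
            f"categories={sorted(categories)}"
        )
    kept: list[ScoredBox] = []
    for d in sorted(dets, key=_sort_key):
        if all(iou(d.box, k.box) <= cfg.dedup_iou_threshold for k in kept):
            kept.append(d)
    return kept


def _overlaps(a: Box3D, b: Box3D, cfg: FusionConfig) -> bool:
    if cfg.cross_model_overlap_rule == "positive-intersection":
        return a.intersection_volume(b) > 0
    return iou(a, b) > cfg.cross_model_iou_threshold


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def fuse_models(
    type_dets: Sequence[ScoredBox],
    disp_dets: Sequence[ScoredBox],
    loc_dets: Sequence[ScoredBox],
    cfg: FusionConfig | None = None,
) -> list[FusedDetection]:
    """Merge the three category models' (already de-duplicated) outputs.

    Builds the cross-model overlap graph, takes connected components,
    drops components supported by a single model, and merges each
    survivor through the union of its best per-model boxes. Returns
    fused detections sorted by descending score.
    """
    cfg = cfg or FusionConfig()
    by_slot = {"type": list(type_dets), "displacement": list(disp_dets), "location": list(loc_dets)}
    for slot, dets in by_slot.items():
        bad = [d for d in dets if d.category != slot]
        if bad:
            raise ValueError(f"detection with category {bad[0].category!r} passed in the {slot} slot")
    boxes: list[ScoredBox] = [d for dets in by_slot.values() for d in dets]
    if not boxes:
        return []
    scan_ids = {d.scan_id for d in boxes if d.scan_id is not None}
    if len(scan_ids) > 1:
        raise ValueError(f"fuse_models expects detections from one scan, got {sorted(scan_ids)}")
    scan_id = scan_ids.pop() if scan_ids else None

    dsu = _DSU(len(boxes))
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if boxes[i].model_id == boxes[j].model_id:
                continue
            if _overlaps(boxes[i].box, boxes[j].box, cfg):
                dsu.union(i, j)

    components: dict[int, list[ScoredBox]] = {}
    for i, d in enumerate(boxes):
        components.setdefault(dsu.find(i), []).append(d)

    fused: list[FusedDetection] = []
    for comp in components.values():
        models = {d.model_id for d in comp}
        if len(models) < 2:
            continue
        # best box per model present; its category provides that label
        reps: dict[str, ScoredBox] = {}
        for model in sorted(models):
            candidates = [d for d in comp if d.model_id == model]
            reps[model] = min(candidates, key=_sort_key)
        rep_list = list(reps.values())
        union_box = rep_list[0].box
        for r in rep_list[1:]:
            union_box = union_box.union_with(r.box)
        labels = {c: UNKNOWN for c in CATEGORIES}
        source_scores: dict[str, float] = {}
        for r in rep_list:
            labels[r.category] = r.label
            source_scores[r.category] = r.score
        scores = [r.score for r in rep_list]
        agg = max(scores) if cfg.score_aggregation == "max" else sum(scores) / len(scores)
        fused.append(
            FusedDetection(
                box=union_box,
                label=CWISLabel(**labels),
                score=agg,
                contributors=tuple(sorted(reps)),
                source_scores=source_scores,
                scan_id=scan_id,
            )
        )
    fused.sort(key=lambda f: (-f.score, f.box.min_corner, f.box.max_corner))
    return fused


def apply_score_threshold(dets: Iterable[FusedDetection], threshold: float) -> list[FusedDetection]:
    """Keep fused detections with score >= threshold (the operating point)."""
    return [d for d in dets if d.score >= threshold]
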