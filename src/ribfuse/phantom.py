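"""Synthetic rib-cage phantoms and a noisy detector simulator.

No CT data ships with this package; instead, the phantom module builds
numbered rib-cage label maps with planted, fully ground-truthed CWIS
fractures, and simulates the three category detectors' raw outputs over
them. Every downstream stage (fusion, rib assignment, evaluation,
agreement) is thereby testable end-to-end against known truth.

Geometry is deliberately schematic: ribs are tubes along elliptical
arcs on a thoracic ellipsoid, numbered 1-12 per side cranial to
caudal. Downstream code consumes only label maps and coordinates, so
anatomical realism beyond topology and spacing is unnecessary. Fracture
location (anterior/lateral/posterior) is derived from the arc-length
fraction from the spine: first third posterior, middle third lateral,
last third anterior — a simulation convention, not a clinical rule.

The detector simulator draws its *detection events* and *false
findings* from streams keyed by the seed alone, while jitter, box
sizes, label confusion and scores come from per-category streams. The
three category heads therefore hit (and hallucinate) the same findings
— as real models looking at the same image do — so the ensemble's
fused sensitivity and false-positive rate track the profile's nominal
values instead of being distorted by the >=2-model consensus rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cwis import CATEGORIES, VOCABULARY, CWISLabel
from .evaluate import ReferenceFracture
from .fusion import Box3D, ScoredBox
from .ribs import RibLabelMap

__all__ = [
    "PhantomSpec",
    "DetectorProfile",
    "uniform_confusion",
    "generate_phantom",
    "simulate_detector_outputs",
    "simulate_scan",
]

# Class frequencies used by default for planted fractures: simple and
# undisplaced fractures dominate, complex fractures are rare, and
# lateral/posterior sites outnumber anterior ones.
DEFAULT_FREQUENCIES: dict[str, dict[str, float]] = {
    "type": {"simple": 0.70, "wedge": 0.20, "complex": 0.10},
    "displacement": {"undisplaced": 0.55, "offset": 0.25, "displaced": 0.20},
    "location": {"anterior": 0.20, "lateral": 0.40, "posterior": 0.40},
}


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic scan.

    The defaults give a 128^3 grid at 2 mm isotropic spacing, a 12-pair
    cage of 4 mm-radius rib tubes, and 9 fractures per scan (the
    per-scan fracture prevalence of a typical blunt-trauma validation
    set), sampled from :data:`DEFAULT_FREQUENCIES` with centers kept at
    least 30 mm apart so reference spheres stay unambiguous.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_rib_pairs: int = 12
    rib_radius_mm: float = 4.0
    n_fractures: int = 9
    frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_FREQUENCIES.items()}
    )
    reference_radius_mm: float = 10.0
    min_fracture_sep_mm: float = 30.0
    split_displaced: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rib_pairs not in (11, 12):
            raise ValueError("n_rib_pairs must be 11 or 12")
        for cat in CATEGORIES:
            freqs = self.frequencies[cat]
            if set(freqs) != set(VOCABULARY[cat]):
                raise ValueError(f"frequencies for {cat} must cover {VOCABULARY[cat]}")
            if not math.isclose(sum(freqs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"frequencies for {cat} must sum to 1")


def _rib_centerline(
    spec: PhantomSpec, pair_index: int, side: str, n_points: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """Centerline points (mm) and arc-length fractions of one rib.

    The rib follows an elliptical arc in the axial plane from near the
    spine (posterior) around to near the sternum (anterior), drooping
    caudally toward the front; pairs are stacked along z.
    """
    extent = np.array(spec.shape) * np.array(spec.spacing)
    cx, cy = extent[0] / 2, extent[1] / 2
    ax, ay = 0.38 * extent[0], 0.30 * extent[1]
    z_lo, z_hi = 0.12 * extent[2], 0.86 * extent[2]
    z0 = z_lo + pair_index * (z_hi - z_lo) / (spec.n_rib_pairs - 1)
    droop = 0.03 * extent[2]

    theta = np.linspace(0.08 * math.pi, 0.92 * math.pi, n_points)
    sign = 1.0 if side == "right" else -1.0
    x = cx + sign * ax * np.sin(theta)
    y = cy + ay * np.cos(theta)  # +y = posterior (spine side)
    seg = np.hypot(np.diff(x), np.diff(y))
    t = np.concatenate([[0.0], np.cumsum(seg)])
    t /= t[-1]
    z = z0 + droop * t
    return np.column_stack([x, y, z]), t


def _ball_offsets(radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Integer voxel offsets within a physical sphere of given radius."""
    r_vox = [int(math.ceil(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    d2 = ((offs * np.asarray(spacing)) ** 2).sum(axis=1)
    return offs[d2 <= radius_mm**2]


def _stamp(grid: np.ndarray, points_mm: np.ndarray, offsets: np.ndarray,
           spacing: Sequence[float], value: int) -> None:
    vox = np.unique(np.round(points_mm / np.asarray(spacing)).astype(int), axis=0)
    idx = (vox[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    idx = idx[ok]
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = value


def _carve(grid: np.ndarray, center_mm: np.ndarray, radius_mm: float,
           spacing: Sequence[float], label: int) -> None:
    offsets = _ball_offsets(radius_mm, spacing)
    c = np.round(center_mm / np.asarray(spacing)).astype(int)
    idx = c[None, :] + offsets
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    idx = idx[ok]
    sel = grid[idx[:, 0], idx[:, 1], idx[:, 2]] == label
    idx = idx[sel]
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = 0


def _location_from_arc(t: float) -> str:
    if t < 1 / 3:
        return "posterior"
    if t < 2 / 3:
        return "lateral"
    return "anterior"


def generate_phantom(
    spec: PhantomSpec, scan_id: str = "phantom-0"
) -> tuple[RibLabelMap, list[ReferenceFracture]]:
    """Build one numbered rib-cage label map with planted fractures.

    Rib labels are 1-12 left, 13-24 right, cranial to caudal. Fracture
    centers are sampled on rib centerlines (so each center voxel carries
    its rib's label), with type/displacement drawn from the spec's
    frequency tables and location determined by the arc-length third.
    With ``split_displaced`` the rib of a 'displaced' fracture is carved
    into two same-label fragments around the fracture gap. Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.zeros(spec.shape, dtype=np.int16)
    tube_offsets = _ball_offsets(spec.rib_radius_mm, spec.spacing)

    centerlines: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for pair in range(spec.n_rib_pairs):
        for side, base in (("left", 1), ("right", 13)):
            label = base + pair
            pts, t = _rib_centerline(spec, pair, side)
            centerlines[label] = (pts, t)
            _stamp(grid, pts, tube_offsets, spec.spacing, label)

    # location frequencies steer which arc third a fracture lands in
    loc_freqs = spec.frequencies["location"]
    type_vals = list(VOCABULARY["type"])
    disp_vals = list(VOCABULARY["displacement"])
    loc_vals = list(VOCABULARY["location"])

    refs: list[ReferenceFracture] = []
    centers_mm: list[np.ndarray] = []
    labels_avail = sorted(centerlines)
    for _ in range(spec.n_fractures):
        placed = False
        for _attempt in range(500):
            rib = int(rng.choice(labels_avail))
            loc = str(rng.choice(loc_vals, p=[loc_freqs[v] for v in loc_vals]))
            third = {"posterior": 0, "lateral": 1, "anterior": 2}[loc]
            t_frac = rng.uniform(third / 3 + 0.03, (third + 1) / 3 - 0.03)
            pts, t = centerlines[rib]
            k = int(np.searchsorted(t, t_frac))
            center_mm = pts[min(k, len(pts) - 1)]
            if all(
                np.linalg.norm(center_mm - c) >= spec.min_fracture_sep_mm for c in centers_mm
            ):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {spec.n_fractures} fractures at least "
                f"{spec.min_fracture_sep_mm} mm apart; reduce n_fractures or separation"
            )
        centers_mm.append(center_mm)
        ftype = str(rng.choice(type_vals, p=[spec.frequencies["type"][v] for v in type_vals]))
        disp = str(rng.choice(disp_vals, p=[spec.frequencies["displacement"][v] for v in disp_vals]))
        center_vox = tuple(float(v) for v in np.round(center_mm / np.asarray(spec.spacing)))
        refs.append(
            ReferenceFracture(
                center=center_vox,
                label=CWISLabel(type=ftype, displacement=disp, location=loc),
                rib=rib,
                radius_mm=spec.reference_radius_mm,
                scan_id=scan_id,
            )
        )

    if spec.split_displaced:
        gap_radius = 1.6 * spec.rib_radius_mm
        for ref, c_mm in zip(refs, centers_mm):
            if ref.label.displacement == "displaced":
                _carve(grid, c_mm, gap_radius, spec.spacing, ref.rib)

    return RibLabelMap(grid=grid, spacing=spec.spacing), refs


def uniform_confusion(accuracy: float, category: str) -> dict[str, dict[str, float]]:
    """Label confusion with given per-class accuracy, errors spread
    uniformly over the other two values of the category."""
    vals = VOCABULARY[category]
    off = (1.0 - accuracy) / (len(vals) - 1)
    return {v: {w: (accuracy if w == v else off) for w in vals} for v in vals}


@dataclass
class DetectorProfile:
    """Behaviour of the simulated category detectors.

    sensitivity
        Probability that a fracture is found; a float applies to all
        three category heads, a dict sets per-category values. Detection
        events share one underlying uniform draw per fracture, so heads
        with equal sensitivity hit exactly the same fractures.
    mean_fp
        Mean number of false findings per scan (Poisson); false findings
        are shared across heads and placed on rib voxels (a configurable
        fraction off-rib).
    jitter_sd_mm / box_size_mm
        Per-axis Gaussian center jitter, and the uniform range of box
        edge lengths, in millimetres.
    confusion
        Per-category label confusion (row-stochastic, true -> emitted);
        None means labels are emitted faithfully.
    tp_score / fp_score
        Beta(a, b) parameters of the probability scores for hits and
        false findings.
    """

    sensitivity: float | Mapping[str, float] = 0.8
    mean_fp: float = 1.11
    jitter_sd_mm: float = 2.0
    box_size_mm: tuple[float, float] = (12.0, 24.0)
    confusion: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None
    tp_score: tuple[float, float] = (6.0, 2.0)
    fp_score: tuple[float, float] = (2.0, 4.0)
    off_rib_fraction: float = 0.0
    fp_min_sep_mm: float = 40.0
    seed: int = 0

    def sensitivity_for(self, category: str) -> float:
        s = self.sensitivity[category] if isinstance(self.sensitivity, Mapping) else self.sensitivity
        if not 0.0 <= s <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")
        return float(s)

    def confusion_row(self, category: str, true_label: str) -> list[float]:
        vals = VOCABULARY[category]
        if self.confusion is None:
            return [1.0 if v == true_label else 0.0 for v in vals]
        row = self.confusion[category][true_label]
        p = [float(row[v]) for v in vals]
        if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
            raise ValueError(f"confusion row for {category}/{true_label} must sum to 1")
        return p

    def __post_init__(self) -> None:
        if self.mean_fp < 0:
            raise ValueError("mean_fp must be non-negative")
        if not 0.0 <= self.off_rib_fraction <= 1.0:
            raise ValueError("off_rib_fraction must lie in [0, 1]")


def _shared_events(
    refs: Sequence[ReferenceFracture], ribs: RibLabelMap, profile: DetectorProfile
) -> tuple[np.ndarray, list[np.ndarray], list[bool]]:
    """Detection uniforms and false-finding locations, shared across heads."""
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0]))
    u = rng.uniform(size=len(refs))
    n_fp = int(rng.poisson(profile.mean_fp))
    on_rib = np.flatnonzero(ribs.grid.ravel() > 0)
    off_rib = None
    spacing = np.asarray(ribs.spacing)
    # false findings are distinct findings: keep them clear of the true
    # fractures and of each other, so the nominal FP rate survives fusion
    occupied_mm = [np.asarray(r.center) * spacing for r in refs]
    fp_centers: list[np.ndarray] = []
    fp_off: list[bool] = []
    for _ in range(n_fp):
        off = bool(rng.uniform() < profile.off_rib_fraction)
        pool = on_rib
        if off:
            if off_rib is None:
                off_rib = np.flatnonzero(ribs.grid.ravel() == 0)
            pool = off_rib
        center = None
        for _attempt in range(100):
            flat = int(rng.choice(pool))
            cand = np.array(np.unravel_index(flat, ribs.shape), dtype=float)
            cand_mm = cand * spacing
            if all(np.linalg.norm(cand_mm - o) >= profile.fp_min_sep_mm for o in occupied_mm):
                center = cand
                break
        if center is None:
            continue  # scan too crowded for another separated false finding
        occupied_mm.append(center * spacing)
        fp_centers.append(center)
        fp_off.append(off)
    return u, fp_centers, fp_off


def _make_box(
    center_vox: np.ndarray,
    size_mm: np.ndarray,
    spacing: Sequence[float],
    shape: Sequence[int],
) -> Box3D:
    half = size_mm / (2 * np.asarray(spacing))
    lo = np.floor(center_vox - half).astype(int)
    hi = np.ceil(center_vox + half).astype(int)
    lo = np.clip(lo, 0, np.asarray(shape) - 1)
    hi = np.clip(hi, lo + 1, np.asarray(shape))
    return Box3D(tuple(lo), tuple(hi))


def simulate_detector_outputs(
    refs: Sequence[ReferenceFracture],
    ribs: RibLabelMap,
    profile: DetectorProfile,
    category: str,
) -> list[ScoredBox]:
    """Raw output of one category head over one scan.

    Each reference is emitted with the category's sensitivity as a box
    centered at the jittered fracture center, labeled via the confusion
    row of its true label, and scored from the TP score distribution;
    Poisson false findings are added on (mostly) rib locations with FP
    scores and uniform labels. Deterministic given ``profile.seed``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    cat_index = CATEGORIES.index(category)
    u, fp_centers, _ = _shared_events(refs, ribs, profile)
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 1 + cat_index]))
    sens = profile.sensitivity_for(category)
    vals = list(VOCABULARY[category])
    spacing = np.asarray(ribs.spacing)
    scan_id = refs[0].scan_id if refs else None

    out: list[ScoredBox] = []
    for ref, ui in zip(refs, u):
        if ui >= sens:
            continue
        jitter = rng.normal(0.0, profile.jitter_sd_mm, size=3) / spacing
        size = rng.uniform(*profile.box_size_mm, size=3)
        label = str(rng.choice(vals, p=profile.confusion_row(category, ref.label[category])))
        score = float(rng.beta(*profile.tp_score))
        box = _make_box(np.asarray(ref.center) + jitter, size, ribs.spacing, ribs.shape)
        out.append(ScoredBox(box=box, score=score, label=label, category=category,
                             model_id=f"{category}-model", scan_id=scan_id))
    for c in fp_centers:
        jitter = rng.normal(0.0, profile.jitter_sd_mm, size=3) / spacing
        size = rng.uniform(*profile.box_size_mm, size=3)
        label = str(rng.choice(vals))
        score = float(rng.beta(*profile.fp_score))
        box = _make_box(c + jitter, size, ribs.spacing, ribs.shape)
        out.append(ScoredBox(box=box, score=score, label=label, category=category,
                             model_id=f"{category}-model", scan_id=scan_id))
    return out


def simulate_scan(
    refs: Sequence[ReferenceFracture], ribs: RibLabelMap, profile: DetectorProfile
) -> dict[str, list[ScoredBox]]:
    """All three category heads' raw outputs for one scan."""
    return {c: simulate_detector_outputs(refs, ribs, profile, c) for c in CATEGORIES}
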