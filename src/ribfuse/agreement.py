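"""Interobserver agreement on rib-fracture annotation and classification.

Two observers annotate the same scans independently; fractures seen by
both are paired by spatial matching of their 10 mm annotation spheres.
Chance-corrected agreement on the CWIS labels of mutual fractures is
quantified with Cohen's kappa (complete pairs) and Krippendorff's alpha
(which also accommodates records where one observer's label is
missing), each with a percentile-bootstrap 95% confidence interval and
a qualitative interpretation band.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cwis import CATEGORIES
from .evaluate import ReferenceFracture

__all__ = [
    "ObserverOverlap",
    "AgreementResult",
    "match_observers",
    "kappa_statistic",
    "alpha_statistic",
    "cohen_kappa",
    "krippendorff_alpha",
    "bootstrap_ci",
    "interpret_agreement",
    "disagreement_counts",
    "agreement_table",
]


@dataclass(frozen=True)
class ObserverOverlap:
    """Spatial overlap of two observers' annotation sets."""

    both: int
    only_1: int
    only_2: int

    @property
    def union(self) -> int:
        return self.both + self.only_1 + self.only_2


def _dist_mm(a: Sequence[float], b: Sequence[float], spacing: Sequence[float]) -> float:
    return math.sqrt(sum(((x - y) * s) ** 2 for x, y, s in zip(a, b, spacing)))


def match_observers(
    ann1: Sequence[ReferenceFracture],
    ann2: Sequence[ReferenceFracture],
    spacing: Sequence[float],
) -> tuple[ObserverOverlap, pd.DataFrame]:
    """Pair the two observers' fracture annotations spatially.

    Two annotations of the same scan refer to the same fracture iff
    their spheres intersect (center distance <= sum of radii, in mm).
    Matching is one-to-one and greedy by ascending center distance.
    Returns overlap counts and a paired-label table with one row per
    fracture in the union; labels of the unseen side are missing (NaN).
    """
    pairs: list[tuple[float, int, int]] = []
    for i, a in enumerate(ann1):
        for j, b in enumerate(ann2):
            if a.scan_id != b.scan_id:
                continue
            d = _dist_mm(a.center, b.center, spacing)
            if d <= a.radius_mm + b.radius_mm:
                pairs.append((d, i, j))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matched.append((i, j))

    rows = []
    for i, j in matched:
        row: dict[str, object] = {"scan_id": ann1[i].scan_id, "seen_by": "both"}
        for cat in CATEGORIES:
            row[f"obs1_{cat}"] = ann1[i].label[cat]
            row[f"obs2_{cat}"] = ann2[j].label[cat]
        rows.append(row)
    for i, a in enumerate(ann1):
        if i not in used1:
            row = {"scan_id": a.scan_id, "seen_by": "observer_1"}
            for cat in CATEGORIES:
                row[f"obs1_{cat}"] = a.label[cat]
                row[f"obs2_{cat}"] = None
            rows.append(row)
    for j, b in enumerate(ann2):
        if j not in used2:
            row = {"scan_id": b.scan_id, "seen_by": "observer_2"}
            for cat in CATEGORIES:
                row[f"obs1_{cat}"] = None
                row[f"obs2_{cat}"] = b.label[cat]
            rows.append(row)
    overlap = ObserverOverlap(
        both=len(matched), only_1=len(ann1) - len(used1), only_2=len(ann2) - len(used2)
    )
    columns = ["scan_id", "seen_by"] + [f"obs{k}_{c}" for c in CATEGORIES for k in (1, 2)]
    return overlap, pd.DataFrame(rows, columns=columns)


def _complete_pairs(labels1: Sequence, labels2: Sequence) -> tuple[list, list]:
    l1, l2 = [], []
    for a, b in zip(labels1, labels2):
        if a is None or b is None or (isinstance(a, float) and math.isnan(a)) or (
            isinstance(b, float) and math.isnan(b)
        ):
            continue
        l1.append(a)
        l2.append(b)
    return l1, l2


def kappa_statistic(labels1: Sequence, labels2: Sequence) -> float:
    """Cohen's kappa for two raters on nominal labels.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    rate and p_e the chance agreement from the raters' marginal label
    frequencies. Records with a missing label are excluded. When both
    raters use a single identical label throughout (p_e = 1), agreement
    is perfect and kappa is reported as 1.
    """
    l1, l2 = _complete_pairs(labels1, labels2)
    n = len(l1)
    if n < 2:
        raise ValueError("kappa needs at least two complete paired records")
    p_o = sum(a == b for a, b in zip(l1, l2)) / n
    c1, c2 = Counter(l1), Counter(l2)
    p_e = sum(c1[v] * c2.get(v, 0) for v in c1) / n**2
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def alpha_statistic(labels1: Sequence, labels2: Sequence) -> float:
    """Krippendorff's alpha (nominal metric) for two raters with missing data.

    alpha = 1 - D_o/D_e computed from the coincidence matrix: each unit
    with both ratings contributes its ordered label pairs, weighted by
    1/(m_u - 1); units with a single rating contribute nothing.
    """
    l1, l2 = _complete_pairs(labels1, labels2)
    if not l1:
        raise ValueError("alpha needs at least one pairable unit")
    values = sorted({*l1, *l2})
    idx = {v: k for k, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for a, b in zip(l1, l2):
        # two ratings per unit -> two ordered pairs, each weighted 1/(m-1)=1
        coincidence[idx[a], idx[b]] += 1
        coincidence[idx[b], idx[a]] += 1
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    if n <= 1:
        raise ValueError("alpha needs more than one pairable value in total")
    d_o = (n - np.trace(coincidence)) / n
    d_e = (n * n - (n_c**2).sum()) / (n * (n - 1))
    if d_e == 0:
        return 1.0
    return float(1 - d_o / d_e)


@dataclass(frozen=True)
class AgreementResult:
    """Agreement statistic with bootstrap CI and interpretation band."""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    interpretation: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


# Banding follows the convention where 0.61-0.80 is "substantial"
# agreement and higher bands split at 0.90; alternative Landis-Koch
# labels are selectable.
_SCALES: dict[str, list[tuple[float, str]]] = {
    "default": [
        (0.0, "Poor"),
        (0.20, "Slight"),
        (0.40, "Fair"),
        (0.60, "Moderate"),
        (0.80, "Substantial"),
        (0.90, "Strong"),
        (1.0, "Almost perfect"),
    ],
    "landis-koch": [
        (0.0, "Poor"),
        (0.20, "Slight"),
        (0.40, "Fair"),
        (0.60, "Moderate"),
        (0.80, "Substantial"),
        (1.0, "Almost perfect"),
    ],
}


def interpret_agreement(estimate: float, scale: str = "default") -> str:
    """Qualitative band for an agreement coefficient in [-1, 1].

    The default scale bands (0.60, 0.80] as "Substantial" and
    (0.80, 0.90] as "Strong"; 'landis-koch' is available as an
    alternative published scale.
    """
    if not -1.0 <= estimate <= 1.0:
        raise ValueError("agreement estimates lie in [-1, 1]")
    bands = _SCALES[scale]
    for upper, name in bands:
        if estimate <= upper:
            return name
    return bands[-1][1]


def bootstrap_ci(
    statistic: Callable[[Sequence, Sequence], float],
    labels1: Sequence,
    labels2: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI by resampling units (fractures) with replacement.

    Resamples on which the statistic is undefined are redrawn, up to
    10 * n_boot attempts in total. Deterministic given the seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    l1 = list(labels1)
    l2 = list(labels2)
    n = len(l1)
    rng = np.random.default_rng(seed)
    values = []
    attempts = 0
    while len(values) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic([l1[i] for i in idx], [l2[i] for i in idx])
        except ValueError:
            continue
        if math.isnan(v):
            continue
        values.append(v)
    if not values:
        raise ValueError("statistic undefined on every bootstrap resample")
    low, high = np.percentile(values, [2.5, 97.5])
    return float(low), float(high)


def _result(
    name: str,
    statistic: Callable,
    labels1: Sequence,
    labels2: Sequence,
    n_boot: int,
    seed: int,
    scale: str,
) -> AgreementResult:
    est = statistic(labels1, labels2)
    low, high = bootstrap_ci(statistic, labels1, labels2, n_boot=n_boot, seed=seed)
    low, high = min(low, est), max(high, est)
    return AgreementResult(name, est, low, high, interpret_agreement(est, scale))


def cohen_kappa(
    labels1: Sequence,
    labels2: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
    scale: str = "default",
) -> AgreementResult:
    """Cohen's kappa with percentile-bootstrap 95% CI (complete pairs only)."""
    return _result("kappa", kappa_statistic, labels1, labels2, n_boot, seed, scale)


def krippendorff_alpha(
    labels1: Sequence,
    labels2: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
    scale: str = "default",
) -> AgreementResult:
    """Krippendorff's alpha (nominal) with percentile-bootstrap 95% CI;
    records with one missing label are handled natively (they simply
    contribute no pairable values)."""
    return _result("alpha", alpha_statistic, labels1, labels2, n_boot, seed, scale)


def disagreement_counts(pairs: pd.DataFrame) -> dict[str, int]:
    """Count label disagreements on mutually seen fractures.

    Returns per-category disagreement counts, the total number of
    disagreeing classification tasks (sum over categories), and the
    number of distinct fractures with at least one disagreement.
    """
    both = pairs[pairs["seen_by"] == "both"] if "seen_by" in pairs else pairs
    counts: dict[str, int] = {}
    any_disagree = np.zeros(len(both), dtype=bool)
    for cat in CATEGORIES:
        a = both[f"obs1_{cat}"].to_numpy()
        b = both[f"obs2_{cat}"].to_numpy()
        disagree = a != b
        counts[cat] = int(disagree.sum())
        any_disagree |= disagree
    counts["tasks"] = sum(counts[c] for c in CATEGORIES)
    counts["fractures"] = int(any_disagree.sum())
    return counts


def agreement_table(
    pairs: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-category kappa and alpha with CIs and interpretation —
    the interobserver summary table.

    Kappa is computed on mutual fractures (complete pairs); alpha on all
    records, accommodating one-sided annotations as missing labels.
    """
    rows = []
    for k, cat in enumerate(CATEGORIES):
        l1 = [None if pd.isna(v) else v for v in pairs[f"obs1_{cat}"]]
        l2 = [None if pd.isna(v) else v for v in pairs[f"obs2_{cat}"]]
        kap = cohen_kappa(l1, l2, n_boot=n_boot, seed=seed + 2 * k)
        alp = krippendorff_alpha(l1, l2, n_boot=n_boot, seed=seed + 2 * k + 1)
        rows.append(
            {
                "category": cat,
                "kappa": round(kap.estimate, 2),
                "kappa_ci": f"{kap.ci_low:.2f}-{kap.ci_high:.2f}",
                "alpha": round(alp.estimate, 2),
                "alpha_ci": f"{alp.ci_low:.2f}-{alp.ci_high:.2f}",
                "interpretation": kap.interpretation,
            }
        )
    return pd.DataFrame(rows)
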