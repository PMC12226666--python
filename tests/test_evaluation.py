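"""Detection matching, pooled metrics, per-class tables, operating point."""

import itertools

import numpy as np
import pytest

from ribfuse import (
    CWISLabel,
    DetectionMetrics,
    MatchResult,
    box_intersects_sphere,
    choose_operating_point,
    confusion_matrices,
    detection_metrics,
    match_detections,
    per_class_metrics,
    rib_number_accuracy,
    stratified_metrics,
)
from ribfuse.cwis import UNKNOWN

from conftest import SPACING, box, fused, ref


def exhaustive_max_tp(dets, refs, spacing):
    """Oracle: maximum TP count over all one-to-one matchings."""
    feasible = {
        (i, j)
        for i, d in enumerate(dets)
        for j, r in enumerate(refs)
        if box_intersects_sphere(d.box, r.center, r.radius_mm, spacing)
    }
    best = 0
    for k in range(min(len(dets), len(refs)), 0, -1):
        for dsub in itertools.permutations(range(len(dets)), k):
            for rsub in itertools.combinations(range(len(refs)), k):
                if all((i, j) in feasible for i, j in zip(dsub, rsub)):
                    return k
    return best


class TestMatching:
    def test_centered_detection_is_tp(self):
        d = fused(box(8, 4))
        r = ref((10, 10, 10))
        m = match_detections([d], [r], SPACING)
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 0, 0)

    def test_double_detection_one_tp_one_fp(self):
        d1 = fused(box(8, 4), score=0.9)
        d2 = fused(box(9, 4), score=0.8)
        m = match_detections([d1, d2], [ref((10, 10, 10))], SPACING)
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 1, 0)
        assert m.tp_pairs[0][0] is d1  # higher score takes the reference

    def test_far_detection_fp_and_lone_reference_fn(self):
        m = match_detections([fused(box(50, 4))], [ref((5, 5, 5))], SPACING)
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 1)

    def test_mixed_scans_rejected(self):
        with pytest.raises(ValueError, match="single scan"):
            match_detections(
                [fused(box(0, 4), scan_id="a")], [ref((2, 2, 2), scan_id="b")], SPACING
            )

    def test_count_conservation_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            dets = [
                fused(box(tuple(rng.integers(0, 30, 3)), tuple(rng.integers(2, 10, 3))),
                      score=float(rng.uniform()))
                for _ in range(rng.integers(0, 6))
            ]
            refs = [ref(tuple(rng.integers(0, 35, 3))) for _ in range(rng.integers(0, 6))]
            m = match_detections(dets, refs, SPACING)
            assert m.n_tp + m.n_fn == len(refs)
            assert m.n_tp + m.n_fp == len(dets)

    def test_greedy_tp_count_matches_exhaustive(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            dets = [
                fused(box(tuple(rng.integers(0, 30, 3)), tuple(rng.integers(2, 10, 3))),
                      score=float(rng.uniform()))
                for _ in range(rng.integers(1, 6))
            ]
            refs = [ref(tuple(rng.integers(0, 35, 3))) for _ in range(rng.integers(1, 6))]
            m = match_detections(dets, refs, SPACING)
            assert m.n_tp == exhaustive_max_tp(dets, refs, SPACING)

    def test_anisotropic_spacing_respected(self):
        # 5 voxels away along z at 5 mm spacing = 25 mm > 10 mm radius
        r = ref((10, 10, 15))
        d = fused(box((9, 9, 9), 2))  # closest z face at voxel 11 -> 4*5=20mm away
        assert not box_intersects_sphere(d.box, r.center, r.radius_mm, (2, 2, 5))
        assert box_intersects_sphere(d.box, r.center, r.radius_mm, (2, 2, 2))


def counts_to_matches(tp, fp, fn, n_scans=1):
    """Build geometrically real MatchResults realizing given pooled counts."""
    matches = []
    per = [(tp // n_scans + (1 if k < tp % n_scans else 0),
            fp // n_scans + (1 if k < fp % n_scans else 0),
            fn // n_scans + (1 if k < fn % n_scans else 0)) for k in range(n_scans)]
    for k, (t, f, n) in enumerate(per):
        pairs = [(fused(box((40 * i, 0, 0), 4)), ref((40 * i + 2, 2, 2))) for i in range(t)]
        fps = [fused(box((40 * i + 20, 0, 0), 2)) for i in range(f)]
        fns = [ref((40 * (t + i) + 2, 50, 2)) for i in range(n)]
        matches.append(MatchResult(f"s{k}", pairs, fps, fns))
    return matches


class TestDetectionMetrics:
    def test_abstract_internal_worked_example(self):
        m = detection_metrics(counts_to_matches(tp=80, fn=20, fp=12))
        s = m.summary()
        assert (s["sensitivity_pct"], s["precision_pct"], s["f1_pct"]) == (80, 87, 83)

    def test_fpps_worked_example(self):
        # 27 false positives over 28 scans
        matches = counts_to_matches(tp=28, fp=27, fn=0, n_scans=28)
        assert detection_metrics(matches).summary()["fpps"] == 0.96

    def test_perfect_detection(self):
        m = detection_metrics(counts_to_matches(tp=5, fp=0, fn=0))
        s = m.summary()
        assert (s["sensitivity_pct"], s["precision_pct"], s["f1_pct"], s["fpps"]) == (
            100, 100, 100, 0.0,
        )

    def test_zero_references_reports_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = detection_metrics(counts_to_matches(tp=0, fp=2, fn=0))
        assert m.sensitivity is None and m.f1 is None

    def test_f1_is_harmonic_mean(self):
        m = DetectionMetrics(tp=30, fp=10, fn=20, n_scans=4)
        s, p = m.sensitivity, m.precision
        assert m.f1 == pytest.approx(2 * s * p / (s + p))


class TestPerClassAndConfusion:
    def _mixed_matches(self):
        simple = CWISLabel("simple", "undisplaced", "lateral")
        wedge = CWISLabel("wedge", "offset", "anterior")
        pairs = [
            (fused(box((40 * i, 0, 0), 4), label=simple), ref((40 * i + 2, 2, 2), label=simple))
            for i in range(3)
        ]
        pairs.append(
            (fused(box((200, 0, 0), 4), label=wedge), ref((202, 2, 2), label=wedge))
        )
        fns = [ref((300, 2, 2), label=simple), ref((340, 2, 2), label=wedge)]
        return [MatchResult("s0", pairs, [], fns)]

    def test_sensitivity_by_class(self):
        table = per_class_metrics(self._mixed_matches()).set_index(["category", "value"])
        assert table.loc[("type", "simple"), "sensitivity"] == pytest.approx(0.75)
        assert table.loc[("type", "wedge"), "sensitivity"] == pytest.approx(0.5)

    def test_absent_class_is_nan(self):
        table = per_class_metrics(self._mixed_matches()).set_index(["category", "value"])
        assert np.isnan(table.loc[("type", "complex"), "sensitivity"])

    def test_all_found_single_class(self):
        matches = counts_to_matches(tp=4, fp=0, fn=0)
        table = per_class_metrics(matches).set_index(["category", "value"])
        assert table.loc[("type", "simple"), "sensitivity"] == 1.0
        assert table.loc[("type", "simple"), "precision"] == 1.0

    def test_confusion_diagonal_when_correct(self):
        mats = confusion_matrices(self._mixed_matches())
        t = mats["type"]
        assert t.loc["simple", "simple"] == 3 and t.loc["wedge", "wedge"] == 1
        assert t.to_numpy().sum() == 4  # TP pairs only

    def test_unknown_prediction_lands_in_unknown_column(self):
        lab = CWISLabel("simple", "undisplaced", UNKNOWN)
        pairs = [(fused(box(0, 4), label=lab), ref((2, 2, 2)))]
        mats = confusion_matrices([MatchResult("s", pairs, [], [])])
        assert mats["location"].loc["lateral", UNKNOWN] == 1

    def test_permutation_invariance(self):
        matches = self._mixed_matches()
        m = matches[0]
        permuted = [MatchResult(m.scan_id, m.tp_pairs[::-1], m.fp_detections, m.fn_references)]
        for cat in ("type", "displacement", "location"):
            assert confusion_matrices(matches)[cat].equals(confusion_matrices(permuted)[cat])

    def test_row_sums_equal_per_class_tp(self):
        mats = confusion_matrices(self._mixed_matches())
        assert mats["type"].sum(axis=1).loc["simple"] == 3


class TestRibAccuracy:
    def test_all_correct(self):
        pairs = [(fused(box((40 * i, 0, 0), 4), rib=5), ref((40 * i + 2, 2, 2), rib=5)) for i in range(4)]
        assert rib_number_accuracy([MatchResult("s", pairs, [], [])]) == 1.0

    def test_47_of_50(self):
        pairs = [
            (fused(box((40 * i, 0, 0), 4), rib=5 if i >= 3 else 6), ref((40 * i + 2, 2, 2), rib=5))
            for i in range(50)
        ]
        acc = rib_number_accuracy([MatchResult("s", pairs, [], [])])
        assert acc == pytest.approx(0.94)

    def test_unassigned_detections_excluded(self):
        pairs = [
            (fused(box(0, 4), rib=None), ref((2, 2, 2), rib=5)),
            (fused(box((40, 0, 0), 4), rib=5), ref((42, 2, 2), rib=5)),
        ]
        assert rib_number_accuracy([MatchResult("s", pairs, [], [])]) == 1.0

    def test_no_pairs_undefined(self):
        assert rib_number_accuracy([MatchResult("s", [], [], [])]) is None


class TestOperatingPoint:
    def _scored_scene(self, scores):
        dets, refs = [], []
        for i, s in enumerate(scores):
            dets.append(fused(box((40 * i, 0, 0), 4), score=s, scan_id="s0"))
            refs.append(ref((40 * i + 2, 2, 2), scan_id="s0"))
        return {"s0": dets}, {"s0": refs}

    def test_threshold_keeps_top_fraction(self):
        dets, refs = self._scored_scene([0.9, 0.8, 0.7, 0.6, 0.5])
        t = choose_operating_point(dets, refs, SPACING, 0.8)
        assert t == pytest.approx(0.6)  # top 4 of 5 TPs = sensitivity 0.8

    def test_target_one_returns_min_tp_score(self):
        dets, refs = self._scored_scene([0.9, 0.4])
        assert choose_operating_point(dets, refs, SPACING, 1.0) == pytest.approx(0.4)

    def test_unattainable_target_warns(self):
        dets, refs = self._scored_scene([0.9])
        refs["s0"].append(ref((300, 300, 300), scan_id="s0"))  # never detected
        with pytest.warns(UserWarning, match="unattainable"):
            t = choose_operating_point(dets, refs, SPACING, 1.0)
        assert t < 0.9

    def test_empty_detections_error(self):
        with pytest.raises(ValueError, match="no detections"):
            choose_operating_point({"s0": []}, {"s0": []}, SPACING, 0.5)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        dets = [
            fused(box(tuple(rng.integers(0, 60, 3)), tuple(rng.integers(2, 8, 3))),
                  score=float(rng.uniform()), scan_id="s0")
            for _ in range(12)
        ]
        refs = [ref(tuple(rng.integers(0, 60, 3)), scan_id="s0") for _ in range(8)]
        prev_tp, prev_fp = len(dets) + 1, len(dets) + 1
        for t in sorted({d.score for d in dets}):
            m = match_detections([d for d in dets if d.score >= t], refs, SPACING)
            assert m.n_tp <= prev_tp and m.n_fp <= prev_fp
            prev_tp, prev_fp = m.n_tp, m.n_fp


class TestStratified:
    def test_single_group_equals_pooled(self):
        matches = counts_to_matches(tp=6, fp=2, fn=2, n_scans=2)
        groups = {m.scan_id: "all" for m in matches}
        strat = stratified_metrics(matches, groups)
        assert strat["all"] == detection_metrics(matches)

    def test_two_groups_direct_counts(self):
        matches = counts_to_matches(tp=6, fp=2, fn=2, n_scans=2)
        groups = {"s0": "thin", "s1": "thick"}
        strat = stratified_metrics(matches, groups)
        assert strat["thin"].tp == matches[0].n_tp
        assert strat["thick"].fp == matches[1].n_fp

    def test_unknown_scan_rejected(self):
        matches = counts_to_matches(tp=1, fp=0, fn=0)
        with pytest.raises(KeyError, match="missing from the grouping"):
            stratified_metrics(matches, {})
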