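"""Fuse three category detectors' boxes into CWIS-labeled detections.

Builds a tiny hand-made scene: one fracture seen by all three category
models, one seen by only two (its location becomes "unknown"), and one
spurious single-model box (discarded by the >=2-model consensus rule).
"""

from ribfuse import Box3D, ScoredBox, dedup_within_model, fuse_models


def det(lo, score, category, label):
    return ScoredBox(
        box=Box3D(lo, tuple(v + 10 for v in lo)),
        score=score,
        label=label,
        category=category,
        model_id=f"{category}-model",
    )


type_dets = [
    det((20, 20, 20), 0.92, "type", "simple"),
    det((21, 20, 20), 0.60, "type", "wedge"),  # duplicate, suppressed by NMS
    det((60, 60, 60), 0.85, "type", "complex"),
    det((100, 10, 10), 0.70, "type", "simple"),  # single-model: dropped
]
disp_dets = [
    det((22, 20, 20), 0.88, "displacement", "undisplaced"),
    det((61, 58, 60), 0.80, "displacement", "displaced"),
]
loc_dets = [det((20, 22, 20), 0.75, "location", "lateral")]

type_dets = dedup_within_model(type_dets)
fused = fuse_models(type_dets, disp_dets, loc_dets)

print(f"{len(fused)} fused detections:")
for f in fused:
    print(
        f"  box {f.box.min_corner}->{f.box.max_corner}  score {f.score:.2f}  "
        f"type={f.label.type} displacement={f.label.displacement} "
        f"location={f.label.location}  ({len(f.contributors)} models)"
    )
# The first detection carries a complete CWIS triple; the second has
# location "unknown" because only the type and displacement models saw
# it; the single-model box at (100,10,10) produced no fused detection.
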