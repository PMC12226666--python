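import numpy as np
import pytest

from ribfuse import (
    Box3D,
    CWISLabel,
    DetectorProfile,
    FusedDetection,
    PhantomSpec,
    ReferenceFracture,
    ScoredBox,
    generate_phantom,
)

SPACING = (2.0, 2.0, 2.0)


def box(lo, size):
    lo = tuple(int(v) for v in np.atleast_1d(lo) * np.ones(3, dtype=int))
    size = tuple(int(v) for v in np.atleast_1d(size) * np.ones(3, dtype=int))
    return Box3D(lo, tuple(a + b for a, b in zip(lo, size)))


def scored(b, score, category="type", label=None, model=None):
    labels = {"type": "simple", "displacement": "undisplaced", "location": "lateral"}
    return ScoredBox(
        box=b,
        score=score,
        label=label or labels[category],
        category=category,
        model_id=model or f"{category}-model",
    )


def fused(b, score=0.9, label=None, rib=None, scan_id=None):
    return FusedDetection(
        box=b,
        label=label or CWISLabel("simple", "undisplaced", "lateral"),
        score=score,
        contributors=("type-model", "displacement-model"),
        scan_id=scan_id,
        rib=rib,
    )


def ref(center, label=None, rib=None, scan_id=None, radius=10.0):
    return ReferenceFracture(
        center=tuple(float(c) for c in center),
        label=label or CWISLabel("simple", "undisplaced", "lateral"),
        rib=rib,
        radius_mm=radius,
        scan_id=scan_id,
    )


def random_box(rng, lo_max=40, size_max=12):
    lo = rng.integers(0, lo_max, size=3)
    size = rng.integers(1, size_max, size=3)
    return Box3D(tuple(int(v) for v in lo), tuple(int(a + b) for a, b in zip(lo, size)))


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom scan shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=11), scan_id="shared-0")


@pytest.fixture(scope="session")
def perfect_profile():
    return DetectorProfile(sensitivity=1.0, mean_fp=0.0, jitter_sd_mm=0.0, seed=3)
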