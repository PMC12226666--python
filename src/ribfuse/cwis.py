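"""CWIS rib-fracture label vocabulary.

The Chest Wall Injury Society (CWIS) taxonomy classifies each rib
fracture along three independent categories:

* ``type``: simple, wedge, or complex;
* ``displacement``: undisplaced, offset, or displaced;
* ``location``: anterior, lateral, or posterior (position along the rib).

A fused detection may additionally carry ``"unknown"`` in at most one
category, when only two of the three category-specific detectors agreed
on a finding and the third contributed no box.
"""

from __future__ import annotations

from dataclasses import dataclass

CATEGORIES: tuple[str, ...] = ("type", "displacement", "location")

VOCABULARY: dict[str, tuple[str, ...]] = {
    "type": ("simple", "wedge", "complex"),
    "displacement": ("undisplaced", "offset", "displaced"),
    "location": ("anterior", "lateral", "posterior"),
}

UNKNOWN = "unknown"


def normalize_label(label: str, category: str, *, allow_unknown: bool = False) -> str:
    """Validate *label* against its category vocabulary, case-insensitively.

    Returns the canonical lower-case spelling. Raises ``ValueError`` for
    labels outside the vocabulary (or ``"unknown"`` unless allowed).
    """
    if category not in VOCABULARY:
        raise ValueError(f"unknown CWIS category {category!r}; expected one of {CATEGORIES}")
    canon = str(label).strip().lower()
    if canon == UNKNOWN:
        if allow_unknown:
            return UNKNOWN
        raise ValueError(f"label 'unknown' not allowed for category {category!r} here")
    if canon not in VOCABULARY[category]:
        raise ValueError(
            f"label {label!r} is not a valid {category} value; "
            f"expected one of {VOCABULARY[category]}"
        )
    return canon


@dataclass(frozen=True)
class CWISLabel:
    """A complete CWIS triple: fracture type, displacement and location.

    At most one component may be ``"unknown"`` — a fused detection needs
    agreement of at least two of the three category models, so at most
    one category can be missing.
    """

    type: str
    displacement: str
    location: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "type", normalize_label(self.type, "type", allow_unknown=True))
        object.__setattr__(
            self, "displacement", normalize_label(self.displacement, "displacement", allow_unknown=True)
        )
        object.__setattr__(
            self, "location", normalize_label(self.location, "location", allow_unknown=True)
        )
        n_unknown = sum(v == UNKNOWN for v in self.as_tuple())
        if n_unknown > 1:
            raise ValueError("at most one CWIS component may be 'unknown'")

    def __getitem__(self, category: str) -> str:
        if category not in CATEGORIES:
            raise KeyError(category)
        return getattr(self, category)

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.type, self.displacement, self.location)

    def as_dict(self) -> dict[str, str]:
        return {c: getattr(self, c) for c in CATEGORIES}

    @property
    def is_complete(self) -> bool:
        return UNKNOWN not in self.as_tuple()
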