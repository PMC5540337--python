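"""The WHOPES proportionate hole index (pHI), the field-standard baseline.

The pHI assigns every hole wider than 0.5 cm a template "diameter", bins it
into four size classes (smaller than a thumb, thumb-to-fist, fist-to-head,
larger than a head), and sums hole counts times per-class weights.  Nets
score ``good`` below 64, ``acceptable`` from 64 to 642, and ``too torn``
above 642.

The index ignores hole *location*, which is exactly what the entry-risk
model critiques: a few small roof holes can out-risk much larger damage on
the upper sides while earning a far lower pHI.  This module computes the
pHI so the two assessments can be juxtaposed.

The default per-class weights (1, 23, 196, 578) are the area-derived WHO
guidance values; they are configuration, external to the behavioural model.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Optional, Sequence

from .model import Hole

__all__ = [
    "PhiSizeClass",
    "PhiResult",
    "DEFAULT_WEIGHTS",
    "classify_hole_size",
    "hole_template_diameter_cm",
    "phi_score",
    "GOOD_THRESHOLD",
    "TOO_TORN_THRESHOLD",
]

GOOD_THRESHOLD = 64.0
TOO_TORN_THRESHOLD = 642.0


class PhiSizeClass(str, Enum):
    """The four pHI size classes, by template diameter in cm.

    Boundary diameters assign upward (a 2 cm hole is thumb-fist); holes
    narrower than 0.5 cm are excluded from the count entirely.
    """

    SMALLER_THAN_THUMB = "smaller_than_thumb"  # [0.5, 2) cm
    THUMB_FIST = "thumb_fist"                  # [2, 10) cm
    FIST_HEAD = "fist_head"                    # [10, 25) cm
    LARGER_THAN_HEAD = "larger_than_head"      # >= 25 cm

    @property
    def diameter_range_cm(self) -> tuple:
        return _CLASS_RANGES[self]


_CLASS_RANGES = {
    PhiSizeClass.SMALLER_THAN_THUMB: (0.5, 2.0),
    PhiSizeClass.THUMB_FIST: (2.0, 10.0),
    PhiSizeClass.FIST_HEAD: (10.0, 25.0),
    PhiSizeClass.LARGER_THAN_HEAD: (25.0, float("inf")),
}

#: WHO guidance area-derived weights per size class (external configuration).
DEFAULT_WEIGHTS: Dict[PhiSizeClass, float] = {
    PhiSizeClass.SMALLER_THAN_THUMB: 1.0,
    PhiSizeClass.THUMB_FIST: 23.0,
    PhiSizeClass.FIST_HEAD: 196.0,
    PhiSizeClass.LARGER_THAN_HEAD: 578.0,
}


@dataclass(frozen=True)
class PhiResult:
    """A net's pHI: per-class counts, the index, and the serviceability category."""

    counts: Dict[PhiSizeClass, int]
    excluded: int
    index: float
    category: str  # good | acceptable | too_torn


def classify_hole_size(diameter_cm: float) -> Optional[PhiSizeClass]:
    """Size class containing ``diameter_cm``, or None if below 0.5 cm."""
    if diameter_cm < 0:
        raise ValueError("diameter must be non-negative")
    for cls, (lo, hi) in _CLASS_RANGES.items():
        if lo <= diameter_cm < hi:
            return cls
    return None


def hole_template_diameter_cm(hole: Hole) -> float:
    """The diameter (cm) the pHI template would assign to a hole.

    Field practice holds a round template behind the hole whatever its real
    shape; the longest extent is what gets matched.  This over-states the
    area of elongated holes — part of why the pHI and the entry-risk model
    disagree.
    """
    if hole.shape is not None:
        return hole.shape.longest_extent / 10.0
    return hole.metrics.avg_width / 10.0


def phi_score(
    holes: Sequence[Hole],
    weights: Optional[Dict[PhiSizeClass, float]] = None,
) -> PhiResult:
    """Compute the proportionate hole index of a hole inventory."""
    if weights is None:
        weights = DEFAULT_WEIGHTS
    missing = set(PhiSizeClass) - set(weights)
    if missing:
        raise ValueError(f"weights missing for classes: {sorted(c.value for c in missing)}")
    counts = {cls: 0 for cls in PhiSizeClass}
    excluded = 0
    for hole in holes:
        cls = classify_hole_size(hole_template_diameter_cm(hole))
        if cls is None:
            excluded += 1
        else:
            counts[cls] += 1
    index = float(sum(counts[c] * weights[c] for c in PhiSizeClass))
    if index < GOOD_THRESHOLD:
        category = "good"
    elif index <= TOO_TORN_THRESHOLD:
        category = "acceptable"
    else:
        category = "too_torn"
    return PhiResult(counts=counts, excluded=excluded, index=index, category=category)
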