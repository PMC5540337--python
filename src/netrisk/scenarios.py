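"""Packaged worked scenarios.

Three published demonstration analyses ship with the package so they can be
regenerated at any time:

``fig9``
    A net damaged the way used nets typically are — long narrow tears low on
    the sides (three 300 x 70 mm rectangles in each of FA2-low and FA2-high,
    five in FA3) plus three small 30 x 30 mm squares on the roof.  Totals
    ~6.3 entries/h, ~81 % from the sides; the roof squares alone would still
    admit ~1.2/h despite being ~1 % of the hole area.

``fig10``
    One round hole per functional area sized to carry (approximately) equal
    entry risk: 25 mm on the roof and, per the published equivalents, 63 mm
    (FA2-low), 139 mm (FA2-high) and 307 mm (FA3).  The freshly solved
    equivalent diameters are reported alongside.

``table4``
    Modelled roof entry risk at the minimum / mid-range / maximum template
    diameter of each WHOPES pHI size class, under both a round-hole and a
    square-hole reading of "diameter"; the smallest passable
    smaller-than-thumb hole uses 6 mm because 5 mm is impassable.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import pandas as pd

from .geometry import Circle, Rectangle
from .model import (
    EntryRiskModel,
    Hole,
    NetAssessmentResults,
    equivalent_diameter,
    hole_entry_rate,
)
from .params import DEFAULT_PARAMETERS, FunctionalArea, SpeciesParameters

__all__ = [
    "fig9_holes",
    "fig10_holes",
    "fig10_equivalent_diameters",
    "table4_frame",
    "run_scenario",
    "SCENARIOS",
]


def fig9_holes(params: SpeciesParameters = DEFAULT_PARAMETERS) -> List[Hole]:
    """The 14-hole 'typically damaged net' inventory."""
    holes: List[Hole] = []
    tear = Rectangle(length_mm=300, width_mm=70)
    square = Rectangle(length_mm=30, width_mm=30)
    for fa, n, shape in [
        (FunctionalArea.FA2_LOW, 3, tear),
        (FunctionalArea.FA2_HIGH, 3, tear),
        (FunctionalArea.FA3, 5, tear),
        (FunctionalArea.FA1, 3, square),
    ]:
        for i in range(n):
            holes.append(Hole.from_shape(f"{fa.value.lower()}-{i + 1}", fa, shape, params))
    return holes


def fig9_roof_only(params: SpeciesParameters = DEFAULT_PARAMETERS) -> List[Hole]:
    """Just the three 30 x 30 mm roof squares of the fig9 net."""
    return [h for h in fig9_holes(params) if h.fa is FunctionalArea.FA1]


#: Published round-hole diameters (mm) carrying roughly equal risk per FA.
FIG10_DIAMETERS_MM = {
    FunctionalArea.FA1: 25.0,
    FunctionalArea.FA2_LOW: 63.0,
    FunctionalArea.FA2_HIGH: 139.0,
    FunctionalArea.FA3: 307.0,
}


def fig10_holes(params: SpeciesParameters = DEFAULT_PARAMETERS) -> List[Hole]:
    """One round hole per FA at the published equal-risk diameters."""
    return [
        Hole.from_shape(f"{fa.value.lower()}-round", fa, Circle(diameter_mm=d), params)
        for fa, d in FIG10_DIAMETERS_MM.items()
    ]


def fig10_equivalent_diameters(
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    reference_diameter_mm: float = 25.0,
) -> Dict[FunctionalArea, float]:
    """Solve the equal-risk diameters (mm) afresh from the model.

    The reference is a round roof hole of ``reference_diameter_mm``; each
    side FA's diameter is the root of rate(circle(d), fa) = reference rate.
    """
    reference = Hole.from_shape("ref", FunctionalArea.FA1,
                                Circle(diameter_mm=reference_diameter_mm), params)
    target = hole_entry_rate(reference, params).entries_per_hour
    out = {FunctionalArea.FA1: reference_diameter_mm}
    for fa in (FunctionalArea.FA2_LOW, FunctionalArea.FA2_HIGH, FunctionalArea.FA3):
        out[fa] = equivalent_diameter(target, fa, params)
    return out


#: pHI size-class template diameters (mm): (minimum, mid-range, maximum).
#: The smallest class's minimum uses 6 mm (5 mm is impassable); the open-top
#: class has no maximum and uses 300 mm as its nominal mid-range.
TABLE4_DIAMETERS_MM = {
    "smaller_than_thumb": (6.0, 12.5, 20.0),
    "thumb_fist": (20.0, 60.0, 100.0),
    "fist_head": (100.0, 175.0, 250.0),
    "larger_than_head": (250.0, 300.0, None),
}


def table4_frame(params: SpeciesParameters = DEFAULT_PARAMETERS) -> pd.DataFrame:
    """Roof entry risk across the pHI size classes, round and square readings."""
    rows = []
    for cls, diameters in TABLE4_DIAMETERS_MM.items():
        for point, d in zip(("minimum", "mid_range", "maximum"), diameters):
            if d is None:
                continue
            round_hole = Hole.from_shape("r", FunctionalArea.FA1,
                                         Circle(diameter_mm=d), params)
            square_hole = Hole.from_shape("s", FunctionalArea.FA1,
                                          Rectangle(length_mm=d, width_mm=d), params)
            rows.append(
                {
                    "size_class": cls,
                    "point": point,
                    "diameter_mm": d,
                    "risk_round": hole_entry_rate(round_hole, params).entries_per_hour,
                    "risk_square": hole_entry_rate(square_hole, params).entries_per_hour,
                }
            )
    return pd.DataFrame(rows)


def run_scenario(
    name: str, params: Optional[SpeciesParameters] = None
) -> "NetAssessmentResults | pd.DataFrame":
    """Regenerate a packaged scenario by name (``fig9``, ``fig10``, ``table4``)."""
    params = params or DEFAULT_PARAMETERS
    # scenario inventories are already in entry form; skip re-normalization
    # (fig10 intentionally carries its published 307 mm FA3 hole)
    if name == "fig9":
        return EntryRiskModel(fig9_holes(params), params, normalize=False).fit()
    if name == "fig10":
        return EntryRiskModel(fig10_holes(params), params, normalize=False).fit()
    if name == "table4":
        return table4_frame(params)
    raise ValueError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}")


SCENARIOS = ("fig9", "fig10", "table4")
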