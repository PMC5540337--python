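"""The bed-net entry-risk model.

For each hole the expected hourly number of mosquito entries factorises as

    entries/h = appearances/h x P(encounter | appearance) x P(passage | encounter)

under the *one-mosquito-constantly-present* convention: exactly one mosquito
attacks the net at all times, each entrant being instantly replaced outside.
Risks therefore scale linearly in the number of attacking mosquitoes and in
time.  The appearance rate depends only on the hole's functional area, the
encounter probability on the hole's perimeter + area, and the passage
probability on its average passable width (log-linear, roof holes more
passable than side holes of equal width).

The model treats the net as a perfect sink (exits are ignored) and is
calibrated for untreated netting; insecticide effects are outside its scope.

Use :class:`EntryRiskModel` for the statsmodels-like interface::

    results = EntryRiskModel(holes).fit()
    print(results.summary())

or the module-level functions (``hole_entry_rate``, ``assess_net``, ...) for
one-off calculations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from scipy.optimize import brentq

from .geometry import HoleMetrics, Measured, Rectangle, circle_metrics
from .params import DEFAULT_PARAMETERS, FunctionalArea, SpeciesParameters

__all__ = [
    "Hole",
    "HoleRisk",
    "UnsupportedSplitError",
    "NoSolutionError",
    "appearance_rate",
    "encounter_probability",
    "passage_probability",
    "hole_entry_rate",
    "assess_net",
    "scale_risk",
    "split_long_hole",
    "split_at_fa_boundaries",
    "normalize_holes",
    "equivalent_diameter",
    "EntryRiskModel",
    "NetAssessmentResults",
]


class UnsupportedSplitError(ValueError):
    """A hole exceeds the 300 mm entry limit and cannot be split automatically.

    Raised for shapes other than rectangles and measured-with-length records;
    such holes must be apportioned manually into <= 300 mm components.
    """


class NoSolutionError(ValueError):
    """No hole diameter attains the requested entry rate within the bound."""


@dataclass(frozen=True)
class Hole:
    """One hole on the net: an id, a functional area, and its metrics.

    ``shape`` may be None when metrics were measured directly.
    """

    id: str
    fa: FunctionalArea
    metrics: HoleMetrics
    shape: Optional[object] = None

    @classmethod
    def from_shape(
        cls,
        id: str,
        fa: Union[FunctionalArea, str],
        shape,
        params: SpeciesParameters = DEFAULT_PARAMETERS,
    ) -> "Hole":
        fa = FunctionalArea(fa)
        return cls(
            id=str(id),
            fa=fa,
            shape=shape,
            metrics=shape.metrics(params.impassable_width, params.section_length),
        )


@dataclass(frozen=True)
class HoleRisk:
    """Per-hole decomposition of the entry rate."""

    hole: Hole
    appearances_per_hour: float
    encounter_prob: float
    encounters_per_hour: float
    passage_prob: float
    entries_per_hour: float


# ---------------------------------------------------------------------------
# elementary model terms


def appearance_rate(
    fa: FunctionalArea, params: SpeciesParameters = DEFAULT_PARAMETERS
) -> float:
    """Hourly per-mosquito appearances on a 30x30 cm patch in ``fa``."""
    fa = FunctionalArea(fa)
    try:
        return params.appearances_per_mosquito_hour[fa]
    except KeyError as exc:
        raise ValueError(f"no appearance rate configured for {fa}") from exc


def encounter_probability(
    metrics: HoleMetrics, params: SpeciesParameters = DEFAULT_PARAMETERS
) -> float:
    """Per-appearance probability of encountering the hole.

    Linear in perimeter + area (mm + mm^2), clamped to [0, 1]; the clamp is
    defensive — the largest meaningful (300 mm) hole reaches only ~0.82.
    """
    p = params.encounter_coefficient * (metrics.perimeter + metrics.area)
    return min(max(p, 0.0), 1.0)


def passage_probability(
    avg_width: float,
    orientation: str,
    params: SpeciesParameters = DEFAULT_PARAMETERS,
) -> float:
    """Per-encounter probability of passing through, from average width (mm).

    Zero at or below the impassability threshold; above it, the orientation's
    log-linear model clamped to [0, 1].  Widths beyond ~95 mm (roof) /
    ~175 mm (side) are effectively fully passable.
    """
    if avg_width <= params.impassable_width:
        return 0.0
    line = params.passage_line(orientation)
    p = line.slope * math.log(avg_width) + line.intercept
    return min(max(p, 0.0), 1.0)


def hole_entry_rate(
    hole: Hole, params: SpeciesParameters = DEFAULT_PARAMETERS
) -> HoleRisk:
    """Expected hourly entries through one hole (one mosquito always present)."""
    if hole.metrics is None:
        raise ValueError(f"hole {hole.id!r} has no metrics")
    appearances = appearance_rate(hole.fa, params)
    p_enc = encounter_probability(hole.metrics, params)
    p_pass = passage_probability(hole.metrics.avg_width, hole.fa.orientation, params)
    return HoleRisk(
        hole=hole,
        appearances_per_hour=appearances,
        encounter_prob=p_enc,
        encounters_per_hour=appearances * p_enc,
        passage_prob=p_pass,
        entries_per_hour=appearances * p_enc * p_pass,
    )


# ---------------------------------------------------------------------------
# normalization


def split_long_hole(hole: Hole, max_dim: Optional[float] = None,
                    params: SpeciesParameters = DEFAULT_PARAMETERS) -> List[Hole]:
    """Split a hole longer than the 300 mm sampling unit into equal entries.

    A rectangle of length L > max_dim becomes ``k = ceil(L/max_dim)`` equal
    rectangles of length L/k and the same width, each with its own full
    perimeter (the shared cut edges are counted, mirroring row-wise entry in
    a per-30 cm assessment).  Measured records with a known length are split
    the same way using a rectangle-equivalent of their average width.  Other
    shapes raise :class:`UnsupportedSplitError`.
    """
    if max_dim is None:
        max_dim = params.max_entry_dimension
    shape = hole.shape
    if isinstance(shape, Rectangle) and shape.length_mm > max_dim:
        k = math.ceil(shape.length_mm / max_dim)
        sub = Rectangle(length_mm=shape.length_mm / k, width_mm=shape.width_mm)
        return [
            Hole.from_shape(f"{hole.id}.{i + 1}", hole.fa, sub, params)
            for i in range(k)
        ]
    if isinstance(shape, Measured) and shape.length_mm and shape.length_mm > max_dim:
        k = math.ceil(shape.length_mm / max_dim)
        w = shape.avg_width_mm
        sub = Measured(
            perimeter_mm=2.0 * (shape.length_mm / k + w),
            area_mm2=shape.area_mm2 / k,
            avg_width_mm=w,
            length_mm=shape.length_mm / k,
        )
        return [
            Hole.from_shape(f"{hole.id}.{i + 1}", hole.fa, sub, params)
            for i in range(k)
        ]
    longest = shape.longest_extent if shape is not None else 0.0
    if longest > max_dim:
        raise UnsupportedSplitError(
            f"hole {hole.id!r} ({type(shape).__name__}) is {longest:.0f} mm long; "
            f"only rectangles and measured holes with a length are split "
            f"automatically — apportion it manually into <= {max_dim:.0f} mm parts"
        )
    return [hole]


def split_at_fa_boundaries(
    id: str,
    length_mm: float,
    width_mm: float,
    bottom_height_mm: float,
    params: SpeciesParameters = DEFAULT_PARAMETERS,
) -> List[Hole]:
    """Apportion a vertical side rectangle spanning FA boundaries.

    A tall rectangular tear on the net side is cut at the 300 mm and 600 mm
    height boundaries; each fragment becomes its own hole with its own full
    rectangle metrics, assigned to the functional area of its band.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("dimensions must be positive")
    bounds = [300.0, 600.0]
    top = bottom_height_mm + length_mm
    cuts = [bottom_height_mm] + [b for b in bounds if bottom_height_mm < b < top] + [top]
    holes: List[Hole] = []
    for i, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:])):
        fa = FunctionalArea.from_height("side", lo)
        # the validator keeps width <= length whichever way the fragment ends up
        frag = Rectangle(length_mm=hi - lo, width_mm=width_mm)
        suffix = f".{i + 1}" if len(cuts) > 2 else ""
        holes.append(Hole.from_shape(f"{id}{suffix}", fa, frag, params))
    return holes


def normalize_holes(
    holes: Sequence[Hole],
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    strict: bool = False,
) -> List[Hole]:
    """Apply the entry rules: split oversize rectangles, cap checks.

    With ``strict=True`` non-splittable holes longer than 300 mm raise
    :class:`UnsupportedSplitError`; by default they are kept with a warning
    (several published worked scenarios themselves contain such holes).
    """
    out: List[Hole] = []
    for hole in holes:
        try:
            out.extend(split_long_hole(hole, params=params))
        except UnsupportedSplitError:
            if strict:
                raise
            warnings.warn(
                f"hole {hole.id!r} exceeds the {params.max_entry_dimension:.0f} mm "
                "entry limit and was kept unsplit", stacklevel=2,
            )
            out.append(hole)
    return out


# ---------------------------------------------------------------------------
# net-level assessment


class NetAssessmentResults:
    """Results of an entry-risk assessment of one net.

    Carries the per-hole risk decomposition, per-FA subtotals, the total
    hourly entry rate and the shares by functional area and by roof vs
    sides.  ``scaled(n, hours)`` applies the linear scaling conventions.
    """

    def __init__(
        self,
        hole_risks: Sequence[HoleRisk],
        params: SpeciesParameters,
        n_mosquitoes: float = 1.0,
        hours: float = 1.0,
    ):
        self.hole_risks = list(hole_risks)
        self.params = params
        self.n_mosquitoes = float(n_mosquitoes)
        self.hours = float(hours)

    # -- totals -------------------------------------------------------------

    @property
    def scale(self) -> float:
        return self.n_mosquitoes * self.hours

    @property
    def total_entries_per_hour(self) -> float:
        """Per-mosquito hourly total, before scaling."""
        return float(sum(r.entries_per_hour for r in self.hole_risks))

    @property
    def total_entries(self) -> float:
        """Expected entries for the configured mosquito number and duration."""
        return self.total_entries_per_hour * self.scale

    @property
    def fa_totals(self) -> Dict[FunctionalArea, float]:
        totals = {fa: 0.0 for fa in FunctionalArea}
        for r in self.hole_risks:
            totals[r.hole.fa] += r.entries_per_hour
        return totals

    @property
    def fraction_by_fa(self) -> Dict[FunctionalArea, float]:
        total = self.total_entries_per_hour
        if total == 0:
            return {fa: 0.0 for fa in FunctionalArea}
        return {fa: v / total for fa, v in self.fa_totals.items()}

    @property
    def fraction_roof(self) -> float:
        total = self.total_entries_per_hour
        if total == 0:
            return 0.0
        return self.fa_totals[FunctionalArea.FA1] / total

    @property
    def fraction_sides(self) -> float:
        return 1.0 - self.fraction_roof if self.total_entries_per_hour > 0 else 0.0

    def scaled(self, n_mosquitoes: float, hours: float) -> "NetAssessmentResults":
        """Results under ``n_mosquitoes`` attacking for ``hours`` hours."""
        if n_mosquitoes < 0 or hours < 0:
            raise ValueError("n_mosquitoes and hours must be non-negative")
        return NetAssessmentResults(self.hole_risks, self.params, n_mosquitoes, hours)

    # -- presentation -------------------------------------------------------

    def per_hole_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.hole_risks:
            m = r.hole.metrics
            rows.append(
                {
                    "hole_id": r.hole.id,
                    "fa": r.hole.fa.value,
                    "perimeter_mm": m.perimeter,
                    "area_mm2": m.area,
                    "avg_width_mm": m.avg_width,
                    "appearances_per_hour": r.appearances_per_hour,
                    "encounter_prob": r.encounter_prob,
                    "encounters_per_hour": r.encounters_per_hour,
                    "passage_prob": r.passage_prob,
                    "entries_per_hour": r.entries_per_hour,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "hole_id",
                "fa",
                "perimeter_mm",
                "area_mm2",
                "avg_width_mm",
                "appearances_per_hour",
                "encounter_prob",
                "encounters_per_hour",
                "passage_prob",
                "entries_per_hour",
            ],
        )

    def summary(self) -> str:
        """Human-readable assessment table (rates at 2 dp, shares in %)."""
        lines = ["Bed net entry-risk assessment", "=" * 64]
        df = self.per_hole_frame()
        if len(df):
            show = df[["hole_id", "fa", "avg_width_mm", "entries_per_hour"]].copy()
            show["avg_width_mm"] = show["avg_width_mm"].round(1)
            show["entries_per_hour"] = show["entries_per_hour"].round(2)
            lines.append(show.to_string(index=False))
        else:
            lines.append("(no holes)")
        lines.append("-" * 64)
        for fa in FunctionalArea:
            lines.append(
                f"{fa.value:<9} {self.fa_totals[fa]:8.2f} entries/h"
                f"  ({self.fraction_by_fa[fa] * 100.0:3.0f}%)"
            )
        lines.append(
            f"TOTAL     {self.total_entries_per_hour:8.2f} entries/h"
            f"  (roof {self.fraction_roof * 100.0:.0f}%"
            f" / sides {self.fraction_sides * 100.0:.0f}%)"
        )
        if self.scale != 1.0:
            lines.append(
                f"Scaled:   {self.total_entries:8.2f} entries"
                f" ({self.n_mosquitoes:g} mosquitoes x {self.hours:g} h)"
            )
        lines.append(f"Parameter hash: {self.params.parameter_hash()}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": "netrisk-entry-risk",
            "parameter_hash": self.params.parameter_hash(),
            "n_mosquitoes": self.n_mosquitoes,
            "hours": self.hours,
            "per_hole": self.per_hole_frame().to_dict(orient="records"),
            "fa_totals_per_hour": {fa.value: v for fa, v in self.fa_totals.items()},
            "fraction_by_fa": {fa.value: v for fa, v in self.fraction_by_fa.items()},
            "fraction_roof": self.fraction_roof,
            "fraction_sides": self.fraction_sides,
            "total_entries_per_hour": self.total_entries_per_hour,
            "total_entries": self.total_entries,
            "confidence_limits": None,  # reserved; variance inputs not available
        }

    def plot_fa_shares(self, ax=None):
        """Pie chart of the entry-risk share per functional area."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shares = {fa.value: v for fa, v in self.fraction_by_fa.items() if v > 0}
        if shares:
            ax.pie(list(shares.values()), labels=list(shares.keys()),
                   autopct="%1.0f%%")
        ax.set_title("Entry risk by functional area")
        return ax


class EntryRiskModel:
    """Deterministic entry-rate model for a hole inventory.

    Parameters
    ----------
    holes : sequence of Hole
        The net's hole inventory (normalized on construction by default).
    params : SpeciesParameters, optional
        Model constants; defaults to the *An. gambiae* calibration.
    normalize : bool
        Apply the >300 mm splitting rule on construction.
    strict : bool
        Error (rather than warn) on oversize holes that cannot be split.
    """

    def __init__(
        self,
        holes: Sequence[Hole],
        params: Optional[SpeciesParameters] = None,
        normalize: bool = True,
        strict: bool = False,
    ):
        self.params = params or DEFAULT_PARAMETERS
        self.holes = (
            normalize_holes(holes, self.params, strict) if normalize else list(holes)
        )

    @classmethod
    def from_inventory(cls, path, params: Optional[SpeciesParameters] = None,
                       **kwargs) -> "EntryRiskModel":
        """Build from a JSON/CSV inventory file (see :mod:`netrisk.io`)."""
        from .io import read_inventory

        params = params or DEFAULT_PARAMETERS
        return cls(read_inventory(path, params=params, normalize=False),
                   params=params, **kwargs)

    def fit(self, n_mosquitoes: float = 1.0, hours: float = 1.0) -> NetAssessmentResults:
        """Evaluate the model, returning a :class:`NetAssessmentResults`."""
        risks = [hole_entry_rate(h, self.params) for h in self.holes]
        return NetAssessmentResults(risks, self.params, n_mosquitoes, hours)

    # the model is deterministic; "fitting" is evaluation
    assess = fit


def assess_net(
    holes: Sequence[Hole],
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    normalize: bool = True,
    strict: bool = False,
) -> NetAssessmentResults:
    """Assess a whole net: per-hole rates, per-FA subtotals, total and shares."""
    return EntryRiskModel(holes, params, normalize=normalize, strict=strict).fit()


def scale_risk(
    assessment: NetAssessmentResults, n_mosquitoes: float, hours: float
) -> NetAssessmentResults:
    """Linearly scale an assessment to ``n_mosquitoes`` over ``hours``."""
    return assessment.scaled(n_mosquitoes, hours)


# ---------------------------------------------------------------------------
# equivalent-diameter solver


def _circle_rate(diameter: float, fa: FunctionalArea, params: SpeciesParameters) -> float:
    """Raw entry rate of a round hole of ``diameter`` mm in ``fa``.

    Deliberately bypasses the 300 mm normalization cap: the solver's job is
    to express a risk as an abstract hole size, which may exceed the cap.
    """
    m = circle_metrics(diameter, params.impassable_width)
    return (
        appearance_rate(fa, params)
        * encounter_probability(m, params)
        * passage_probability(m.avg_width, fa.orientation, params)
    )


def equivalent_diameter(
    target_rate: float,
    fa: Union[FunctionalArea, str],
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    bound: float = 2000.0,
    xtol: float = 1e-3,
) -> float:
    """Diameter (mm) of a round hole in ``fa`` with the given entry rate.

    The rate is continuous and strictly increasing in diameter above the
    impassability threshold (once the passage clamp engages the encounter
    term keeps growing), so the root is unique; it is bracketed and solved
    to ``xtol`` mm.  Raises :class:`NoSolutionError` if the target is not
    attainable below ``bound`` mm.
    """
    fa = FunctionalArea(fa)
    if target_rate <= 0:
        raise NoSolutionError("target rate must be positive")
    lo = params.impassable_width
    if _circle_rate(bound, fa, params) < target_rate:
        raise NoSolutionError(
            f"no round hole up to {bound:.0f} mm in {fa.value} reaches "
            f"{target_rate:g} entries/h"
        )
    return float(
        brentq(lambda d: _circle_rate(d, fa, params) - target_rate, lo, bound, xtol=xtol)
    )
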