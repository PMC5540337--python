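"""Hole geometry: perimeter, area and average passable width.

Every quantity the entry-risk model consumes about a hole reduces to three
numbers: the perimeter ``P`` (mm), the open area ``A`` (mm^2) and the average
*passable* width ``w`` (mm).  Width drives the per-encounter passage
probability, so parts of a hole narrower than the impassability threshold
(5 mm for *An. gambiae*) are excluded from the average; a hole whose every
section is that narrow has ``avg_width = 0`` and contributes nothing.

Supported shape descriptions
----------------------------
:class:`Rectangle`, :class:`Circle`, :class:`Ellipse`,
:class:`IsoscelesTriangle`, :class:`PolygonOutline` (a traced outline of an
irregular hole) and :class:`Measured` (pre-measured P/A/w entered directly).
All lengths are millimetres.

The ellipse uses the quadratic-mean perimeter approximation
``2*pi*sqrt((a^2 + b^2)/2)`` (semi-axes ``a``, ``b``), accurate to ~5 % for
aspect ratios up to 3, which covers the large majority of real net holes.
Average width follows the field sectioning procedure: tile the longest axis
into 10 mm sections, read the transverse width at each section midpoint, and
average the midpoints that exceed the threshold.

For irregular outlines the *effective* perimeter is the smaller of the raw
boundary length and the convex-hull perimeter: a deeply crenellated tear has
a huge raw boundary that would absurdly inflate the encounter term, while
the hull tracks what a mosquito skimming the net surface can actually meet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Annotated, Callable, Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from shapely import affinity
from shapely.geometry import LineString, MultiPoint
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "InvalidShapeError",
    "HoleMetrics",
    "WidthProfile",
    "Rectangle",
    "Circle",
    "Ellipse",
    "IsoscelesTriangle",
    "PolygonOutline",
    "Measured",
    "HoleShape",
    "shape_from_dict",
    "average_width",
    "rectangle_metrics",
    "circle_metrics",
    "ellipse_metrics",
    "triangle_metrics",
    "polygon_metrics",
    "convex_hull_perimeter",
    "elliptical_width_profile",
    "triangular_width_profile",
    "polygon_width_profile",
    "DEFAULT_IMPASSABLE_WIDTH",
    "DEFAULT_SECTION_LENGTH",
]

#: Width (mm) at or below which a hole section is impassable to An. gambiae.
DEFAULT_IMPASSABLE_WIDTH = 5.0
#: Length (mm) of the sections used in the average-width procedure (1 cm).
DEFAULT_SECTION_LENGTH = 10.0


class InvalidShapeError(ValueError):
    """Raised for geometrically invalid hole descriptions."""


@dataclass(frozen=True)
class HoleMetrics:
    """The metric triple the entry-risk model consumes.

    ``avg_width == 0`` means the hole is impassable.  For polygon outlines
    the raw boundary length and convex-hull perimeter are retained alongside
    the effective ``perimeter`` for transparency.
    """

    perimeter: float
    area: float
    avg_width: float
    raw_perimeter: Optional[float] = None
    hull_perimeter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.perimeter < 0 or self.area < 0 or self.avg_width < 0:
            raise InvalidShapeError("metrics must be non-negative")

    @property
    def passable(self) -> bool:
        return self.avg_width > 0


@dataclass(frozen=True)
class WidthProfile:
    """Transverse width as a function of position along a hole's longest axis.

    ``width_at(x)`` returns the width (mm) of the hole at position ``x`` in
    ``[0, axis_length]`` measured along the axis of maximal extent.
    """

    axis_length: float
    width_at: Callable[[float], float]
    section_length: float = DEFAULT_SECTION_LENGTH


def average_width(
    profile: WidthProfile,
    threshold: float = DEFAULT_IMPASSABLE_WIDTH,
    section_length: Optional[float] = None,
) -> float:
    """Average passable width of a hole by the midpoint sectioning procedure.

    The longest axis is tiled into consecutive sections of ``section_length``
    (the final partial section, if any, is kept); the width is evaluated at
    each section midpoint and the mean is taken over midpoints strictly wider
    than ``threshold``.  Returns 0.0 if no section qualifies.

    The strict, unrounded comparison is deliberate: it reproduces the field
    procedure's published worked examples without introducing a rounding step
    into the algorithm itself.
    """
    s = profile.section_length if section_length is None else float(section_length)
    if s <= 0:
        raise InvalidShapeError("section_length must be positive")
    if threshold < 0:
        raise InvalidShapeError("threshold must be non-negative")
    L = profile.axis_length
    if L <= 0:
        return 0.0
    starts = np.arange(0.0, L, s)
    ends = np.minimum(starts + s, L)
    mids = (starts + ends) / 2.0
    widths = np.array([float(profile.width_at(float(x))) for x in mids])
    passable = widths[widths > threshold]
    if passable.size == 0:
        return 0.0
    return float(passable.mean())


# ---------------------------------------------------------------------------
# width profiles


def elliptical_width_profile(major_axis: float, minor_axis: float) -> WidthProfile:
    """Width profile of an ellipse along its major axis."""
    a = major_axis / 2.0

    def width_at(x: float) -> float:
        u = (x - a) / a
        return minor_axis * math.sqrt(max(0.0, 1.0 - u * u))

    return WidthProfile(axis_length=major_axis, width_at=width_at)


def triangular_width_profile(base: float, length: float) -> WidthProfile:
    """Width profile of an isosceles triangle along its symmetry axis.

    ``x`` is measured from the apex, so the width grows linearly from 0 at
    the apex to ``base`` at the open end: ``w(x) = base * x / length``.
    """

    def width_at(x: float) -> float:
        return base * x / length

    return WidthProfile(axis_length=length, width_at=width_at)


def _longest_extent_axis(points: np.ndarray) -> tuple[float, float, float]:
    """Return (angle, length, _) of the direction of maximal extent.

    Brute-force rotating-calipers over the convex-hull vertex pairs; hole
    outlines have few vertices so the quadratic scan is immaterial.
    """
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    coords = np.asarray(hull.exterior.coords if hasattr(hull, "exterior") else hull.coords)
    best = (0.0, 0.0)
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[j] - coords[i]
            dist = float(np.hypot(d[0], d[1]))
            if dist > best[1]:
                best = (math.atan2(d[1], d[0]), dist)
    return best[0], best[1], 0.0


def polygon_width_profile(vertices: Sequence[tuple[float, float]]) -> WidthProfile:
    """Width profile of a simple polygon perpendicular to its longest axis.

    The polygon is rotated so the direction of maximal vertex-to-vertex
    extent lies along x; the width at position ``x`` is the total length of
    the polygon's intersection with the vertical line there (multiple lobes
    of a concave outline sum).
    """
    poly = _validated_polygon(vertices)
    angle, _, _ = _longest_extent_axis(np.asarray(poly.exterior.coords))
    rotated = affinity.rotate(poly, -angle, origin=(0, 0), use_radians=True)
    minx, miny, maxx, maxy = rotated.bounds

    def width_at(x: float) -> float:
        cut = LineString([(minx + x, miny - 1.0), (minx + x, maxy + 1.0)])
        return float(rotated.intersection(cut).length)

    return WidthProfile(axis_length=maxx - minx, width_at=width_at)


# ---------------------------------------------------------------------------
# metric functions


def _require_positive(**dims: float) -> None:
    for name, value in dims.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidShapeError(f"{name} must be positive and finite, got {value!r}")


def rectangle_metrics(
    length: float,
    width: float,
    threshold: float = DEFAULT_IMPASSABLE_WIDTH,
) -> HoleMetrics:
    """Metrics of a rectangular hole (``width`` is the lesser dimension)."""
    _require_positive(length=length, width=width)
    if width > length:
        length, width = width, length
    return HoleMetrics(
        perimeter=2.0 * (length + width),
        area=length * width,
        avg_width=width if width > threshold else 0.0,
    )


def circle_metrics(diameter: float, threshold: float = DEFAULT_IMPASSABLE_WIDTH) -> HoleMetrics:
    """Metrics of a round hole; its diameter serves as its width."""
    _require_positive(diameter=diameter)
    return HoleMetrics(
        perimeter=math.pi * diameter,
        area=math.pi * diameter * diameter / 4.0,
        avg_width=diameter if diameter > threshold else 0.0,
    )


def ellipse_metrics(
    major_axis: float,
    minor_axis: float,
    threshold: float = DEFAULT_IMPASSABLE_WIDTH,
    section_length: float = DEFAULT_SECTION_LENGTH,
    narrow_fallback: bool = False,
) -> HoleMetrics:
    """Metrics of an elliptical hole.

    Area is exact (``pi*a*b``); the perimeter uses the quadratic-mean
    approximation ``2*pi*sqrt((a^2+b^2)/2)``, within ~5 % for aspect ratios
    up to 3.  For very narrow ellipses (aspect > 3) ``narrow_fallback=True``
    estimates the perimeter as twice the major axis instead; the default
    keeps the closed form for continuity across the aspect range.
    Average width comes from sectioning the analytic width profile.
    """
    _require_positive(major_axis=major_axis, minor_axis=minor_axis)
    if minor_axis > major_axis:
        raise InvalidShapeError("minor_axis must not exceed major_axis")
    a, b = major_axis / 2.0, minor_axis / 2.0
    perimeter = 2.0 * math.pi * math.sqrt((a * a + b * b) / 2.0)
    if narrow_fallback and major_axis > 3.0 * minor_axis:
        perimeter = 2.0 * major_axis
    return HoleMetrics(
        perimeter=perimeter,
        area=math.pi * a * b,
        avg_width=average_width(
            elliptical_width_profile(major_axis, minor_axis), threshold, section_length
        ),
    )


def triangle_metrics(
    base: float,
    length: float,
    threshold: float = DEFAULT_IMPASSABLE_WIDTH,
    section_length: float = DEFAULT_SECTION_LENGTH,
) -> HoleMetrics:
    """Metrics of an isosceles triangular hole (``length`` apex-to-base)."""
    _require_positive(base=base, length=length)
    leg = math.sqrt(length * length + (base / 2.0) ** 2)
    return HoleMetrics(
        perimeter=base + 2.0 * leg,
        area=base * length / 2.0,
        avg_width=average_width(
            triangular_width_profile(base, length), threshold, section_length
        ),
    )


def _validated_polygon(vertices: Sequence[tuple[float, float]]) -> _ShapelyPolygon:
    if len(vertices) < 3:
        raise InvalidShapeError("polygon outline needs at least 3 vertices")
    poly = _ShapelyPolygon(vertices)
    if not poly.is_valid or poly.area <= 0:
        raise InvalidShapeError("polygon outline must be simple (non-self-intersecting)")
    return poly


def convex_hull_perimeter(vertices: Sequence[tuple[float, float]]) -> float:
    """Perimeter of the convex hull of a vertex set (mm)."""
    if len(vertices) < 3:
        raise InvalidShapeError("need at least 3 vertices")
    hull = MultiPoint([tuple(v) for v in vertices]).convex_hull
    if not isinstance(hull, _ShapelyPolygon):
        raise InvalidShapeError("vertices are collinear; hull is degenerate")
    return float(hull.exterior.length)


def polygon_metrics(
    vertices: Sequence[tuple[float, float]],
    threshold: float = DEFAULT_IMPASSABLE_WIDTH,
    section_length: float = DEFAULT_SECTION_LENGTH,
) -> HoleMetrics:
    """Metrics of an irregular hole from its traced outline.

    Area is the shoelace area of the outline; the effective perimeter is the
    smaller of the raw boundary length and the convex-hull perimeter (both
    retained on the result); average width is sectioned perpendicular to the
    direction of maximal extent.
    """
    poly = _validated_polygon(vertices)
    raw = float(poly.exterior.length)
    hull = float(poly.convex_hull.exterior.length)
    return HoleMetrics(
        perimeter=min(raw, hull),
        area=float(poly.area),
        avg_width=average_width(polygon_width_profile(vertices), threshold, section_length),
        raw_perimeter=raw,
        hull_perimeter=hull,
    )


# ---------------------------------------------------------------------------
# shape records (validated inventory-facing descriptions)


class _Shape(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    def metrics(
        self,
        threshold: float = DEFAULT_IMPASSABLE_WIDTH,
        section_length: float = DEFAULT_SECTION_LENGTH,
    ) -> HoleMetrics:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def longest_extent(self) -> float:  # pragma: no cover - overridden
        """Largest straight-line dimension (mm); the pHI template diameter."""
        raise NotImplementedError


class Rectangle(_Shape):
    shape: Literal["rectangle"] = "rectangle"
    length_mm: float = Field(gt=0)
    width_mm: float = Field(gt=0)

    @model_validator(mode="after")
    def _order_sides(self) -> "Rectangle":
        if self.width_mm > self.length_mm:
            length, width = self.width_mm, self.length_mm
            object.__setattr__(self, "length_mm", length)
            object.__setattr__(self, "width_mm", width)
        return self

    def metrics(self, threshold=DEFAULT_IMPASSABLE_WIDTH, section_length=DEFAULT_SECTION_LENGTH):
        return rectangle_metrics(self.length_mm, self.width_mm, threshold)

    @property
    def longest_extent(self) -> float:
        return self.length_mm


class Circle(_Shape):
    shape: Literal["circle"] = "circle"
    diameter_mm: float = Field(gt=0)

    def metrics(self, threshold=DEFAULT_IMPASSABLE_WIDTH, section_length=DEFAULT_SECTION_LENGTH):
        return circle_metrics(self.diameter_mm, threshold)

    @property
    def longest_extent(self) -> float:
        return self.diameter_mm


class Ellipse(_Shape):
    shape: Literal["ellipse"] = "ellipse"
    major_mm: float = Field(gt=0)
    minor_mm: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_axes(self) -> "Ellipse":
        if self.minor_mm > self.major_mm:
            raise ValueError("minor_mm must not exceed major_mm")
        return self

    def metrics(self, threshold=DEFAULT_IMPASSABLE_WIDTH, section_length=DEFAULT_SECTION_LENGTH):
        return ellipse_metrics(self.major_mm, self.minor_mm, threshold, section_length)

    @property
    def longest_extent(self) -> float:
        return self.major_mm


class IsoscelesTriangle(_Shape):
    shape: Literal["triangle"] = "triangle"
    base_mm: float = Field(gt=0)
    length_mm: float = Field(gt=0)

    def metrics(self, threshold=DEFAULT_IMPASSABLE_WIDTH, section_length=DEFAULT_SECTION_LENGTH):
        return triangle_metrics(self.base_mm, self.length_mm, threshold, section_length)

    @property
    def longest_extent(self) -> float:
        leg = math.sqrt(self.length_mm**2 + (self.base_mm / 2.0) ** 2)
        return max(self.base_mm, leg)


class PolygonOutline(_Shape):
    shape: Literal["polygon"] = "polygon"
    vertices_mm: tuple[tuple[float, float], ...] = Field(min_length=3)

    @model_validator(mode="after")
    def _check_simple(self) -> "PolygonOutline":
        try:
            _validated_polygon(self.vertices_mm)
        except InvalidShapeError as exc:
            raise ValueError(str(exc)) from exc
        return self

    def metrics(self, threshold=DEFAULT_IMPASSABLE_WIDTH, section_length=DEFAULT_SECTION_LENGTH):
        return polygon_metrics(self.vertices_mm, threshold, section_length)

    @property
    def longest_extent(self) -> float:
        _, length, _ = _longest_extent_axis(np.asarray(self.vertices_mm, dtype=float))
        return length


class Measured(_Shape):
    """Pre-measured metrics entered directly (e.g. from a grid template)."""

    shape: Literal["measured"] = "measured"
    perimeter_mm: float = Field(ge=0)
    area_mm2: float = Field(ge=0)
    avg_width_mm: float = Field(ge=0)
    length_mm: Optional[float] = Field(default=None, gt=0)

    def metrics(self, threshold=DEFAULT_IMPASSABLE_WIDTH, section_length=DEFAULT_SECTION_LENGTH):
        w = self.avg_width_mm if self.avg_width_mm > threshold else 0.0
        return HoleMetrics(perimeter=self.perimeter_mm, area=self.area_mm2, avg_width=w)

    @property
    def longest_extent(self) -> float:
        if self.length_mm is not None:
            return self.length_mm
        # rectangle-equivalent estimate from perimeter and average width
        if self.avg_width_mm > 0:
            return max(self.perimeter_mm / 2.0 - self.avg_width_mm, self.avg_width_mm)
        return self.perimeter_mm / 2.0


HoleShape = Annotated[
    Union[Rectangle, Circle, Ellipse, IsoscelesTriangle, PolygonOutline, Measured],
    Field(discriminator="shape"),
]

_SHAPE_CLASSES = {
    "rectangle": Rectangle,
    "circle": Circle,
    "ellipse": Ellipse,
    "triangle": IsoscelesTriangle,
    "polygon": PolygonOutline,
    "measured": Measured,
}


def shape_from_dict(record: dict) -> "Rectangle | Circle | Ellipse | IsoscelesTriangle | PolygonOutline | Measured":
    """Build a validated shape from a tagged dict (``{"shape": "circle", ...}``)."""
    tag = record.get("shape")
    cls = _SHAPE_CLASSES.get(tag)
    if cls is None:
        raise InvalidShapeError(f"unknown shape tag {tag!r}")
    return cls.model_validate(record)
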