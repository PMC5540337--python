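"""Synthetic inventories, polygon outlines, and a stochastic entry simulator.

The generator produces reproducible random hole inventories spanning all
functional areas and shape variants — including sub-threshold (impassable)
holes and >300 mm tears that exercise the normalization rules.  Hole widths
are log-uniform over 1-300 mm, reflecting that small holes dominate real
damage inventories while large tears occur but are rare.

``simulate_entries`` is the stochastic counterpart of the deterministic
rate model and serves as its validation oracle: per hole, appearances over
the exposure are Poisson with the FA's hourly rate, each appearance is
thinned by an independent Bernoulli encounter and then Bernoulli passage.
The thinned sum is again Poisson with mean equal to the deterministic
``entries/h x hours x mosquitoes``, so long-run simulated means must match
the model to Monte-Carlo error.  Appearances are modelled as a homogeneous
process: real activity fluctuates within a session, but only the hourly
expectation enters the risk model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .geometry import (
    Circle,
    Ellipse,
    IsoscelesTriangle,
    Measured,
    PolygonOutline,
    Rectangle,
)
from .model import Hole, hole_entry_rate
from .params import DEFAULT_PARAMETERS, FunctionalArea, SpeciesParameters

__all__ = [
    "GeneratorSpec",
    "generate_inventory",
    "GeneratedPolygon",
    "generate_polygon_hole",
    "simulate_entries",
]

_SHAPE_KINDS = ("rectangle", "circle", "ellipse", "triangle", "polygon", "measured")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random inventory generator.

    ``holes_per_fa`` maps each functional area to a hole count;
    ``shape_mix`` weights the shape variants; widths are drawn log-uniformly
    from ``width_range_mm``; ``aspect_range`` controls hole elongation and
    ``polygon_roughness`` the raggedness of generated outlines.  The same
    seed always yields the same inventory.
    """

    seed: int = 0
    holes_per_fa: Dict[FunctionalArea, int] = field(
        default_factory=lambda: {fa: 3 for fa in FunctionalArea}
    )
    shape_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "rectangle": 0.4,
            "circle": 0.2,
            "ellipse": 0.15,
            "triangle": 0.1,
            "polygon": 0.1,
            "measured": 0.05,
        }
    )
    width_range_mm: tuple = (1.0, 300.0)
    aspect_range: tuple = (1.0, 6.0)
    polygon_roughness: float = 0.25


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def generate_inventory(
    spec: GeneratorSpec, params: SpeciesParameters = DEFAULT_PARAMETERS
) -> List[Hole]:
    """Generate a reproducible random hole inventory (un-normalized)."""
    rng = np.random.default_rng(spec.seed)
    kinds = [k for k in _SHAPE_KINDS if spec.shape_mix.get(k, 0.0) > 0]
    probs = np.array([spec.shape_mix[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    lo, hi = spec.width_range_mm
    holes: List[Hole] = []
    n = 0
    for fa in FunctionalArea:
        for _ in range(spec.holes_per_fa.get(fa, 0)):
            n += 1
            kind = str(rng.choice(kinds, p=probs))
            width = _log_uniform(rng, lo, hi)
            aspect = rng.uniform(*spec.aspect_range)
            if kind == "rectangle":
                shape = Rectangle(length_mm=width * aspect, width_mm=width)
            elif kind == "circle":
                shape = Circle(diameter_mm=width)
            elif kind == "ellipse":
                shape = Ellipse(major_mm=width * aspect, minor_mm=width)
            elif kind == "triangle":
                shape = IsoscelesTriangle(base_mm=width, length_mm=width * aspect)
            elif kind == "polygon":
                gen = generate_polygon_hole(
                    seed=int(rng.integers(2**31)),
                    target_area=math.pi * width * width * aspect / 4.0,
                    elongation=aspect,
                    roughness=spec.polygon_roughness,
                )
                shape = PolygonOutline(vertices_mm=tuple(map(tuple, gen.vertices_mm)))
            else:  # measured
                length = width * aspect
                shape = Measured(
                    perimeter_mm=2.0 * (length + width),
                    area_mm2=length * width,
                    avg_width_mm=width,
                    length_mm=length,
                )
            holes.append(Hole.from_shape(f"gen-{n}", fa, shape, params))
    return holes


@dataclass(frozen=True)
class GeneratedPolygon:
    """A generated outline plus the smooth ellipse it perturbs.

    ``base_major_mm``/``base_minor_mm`` describe the underlying ellipse
    before boundary noise, kept for oracle comparisons of elongation and
    width behaviour.
    """

    vertices_mm: tuple
    target_area_mm2: float
    elongation: float
    base_major_mm: float
    base_minor_mm: float


def generate_polygon_hole(
    seed: int,
    target_area: float,
    elongation: float = 1.0,
    n_vertices: int = 24,
    roughness: float = 0.25,
) -> GeneratedPolygon:
    """Generate a simple star-shaped polygon of roughly ``target_area`` mm^2.

    A radial blob: an ellipse of the requested elongation whose radius is
    modulated by smooth periodic noise of relative amplitude ``roughness``,
    then rescaled so the shoelace area is within 10 % of ``target_area``
    (exact up to the discretization of the outline).  Star-shapedness about
    the centroid guarantees a simple (non-self-intersecting) outline.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    if not (0 <= roughness < 1):
        raise ValueError("roughness must be in [0, 1)")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    # smooth periodic modulation from a few random harmonics
    modulation = np.zeros_like(theta)
    for k in (2, 3, 5):
        modulation += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
    if np.max(np.abs(modulation)) > 0:
        modulation *= roughness / np.max(np.abs(modulation))
    b = math.sqrt(target_area / (math.pi * elongation))
    a = b * elongation
    x = a * np.cos(theta) * (1.0 + modulation)
    y = b * np.sin(theta) * (1.0 + modulation)
    # rescale to the target area using the shoelace formula
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    s = math.sqrt(target_area / area)
    vertices = tuple((float(xi * s), float(yi * s)) for xi, yi in zip(x, y))
    return GeneratedPolygon(
        vertices_mm=vertices,
        target_area_mm2=target_area,
        elongation=elongation,
        base_major_mm=2 * a * s,
        base_minor_mm=2 * b * s,
    )


def simulate_entries(
    holes: Sequence[Hole],
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    hours: float = 1.0,
    n_mosquitoes: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Simulate the appearance -> encounter -> passage chain; count entries.

    Per hole: appearances ~ Poisson(rate x hours x mosquitoes), encounters ~
    Binomial(appearances, p_enc), passages ~ Binomial(encounters, p_pass).
    Returns the total integer number of entries.
    """
    if hours <= 0:
        raise ValueError("hours must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    total = 0
    for hole in holes:
        risk = hole_entry_rate(hole, params)
        appearances = rng.poisson(risk.appearances_per_hour * hours * n_mosquitoes)
        encounters = rng.binomial(appearances, risk.encounter_prob) if appearances else 0
        passages = rng.binomial(encounters, risk.passage_prob) if encounters else 0
        total += int(passages)
    return total
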