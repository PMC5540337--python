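"""Species-specific model constants.

The default parameter set encodes laboratory-derived *Anopheles gambiae*
behaviour around an occupied, untreated rectangular bed net:

* **Appearance rates** — mean number of times one host-seeking mosquito
  appears within ~1-1.5 cm of a 30 cm x 30 cm patch of net per hour, by
  functional area.  Observed hourly appearances for a 200-mosquito cohort
  were 14,450 on the roof (FA1), 1,900 on the bottom 30 cm of the sides
  (FA2-low), 300 on the 30-60 cm band (FA2-high) and 60 on the upper
  two-thirds (FA3); per mosquito that is 72.3 / 9.5 / 1.5 / 0.3.
* **Encounter coefficient** — per appearance, the probability of impinging
  on a hole is ``9e-6 * (perimeter_mm + area_mm2)``.
* **Passage models** — per encounter, the probability of passing through is
  log-linear in the hole's (average) width: ``0.34*ln(w) - 0.55`` on the
  roof, ``0.30*ln(w) - 0.52`` on the sides, clamped to [0, 1].  Both lines
  cross zero near 5 mm, matching the impassability threshold.

Parameters are configuration, not fitted here; other species or net types
can be represented by loading an override file (YAML or JSON) whose keys
mirror the field names below.
"""

from __future__ import annotations

import hashlib
import json
import math
from enum import Enum
from pathlib import Path
from typing import Dict, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "FunctionalArea",
    "PassageLine",
    "SpeciesParameters",
    "OBSERVED_MEAN_APPEARANCES_PER_HOUR",
    "COHORT_SIZE",
]

#: Observed mean hourly appearances for the 200-mosquito laboratory cohort,
#: per 30x30 cm sampling area (raw session means, before FA2 subdivision).
OBSERVED_MEAN_APPEARANCES_PER_HOUR = {"roof": 14450.0, "low_side": 1090.0, "upper_side": 57.0}
#: Number of mosquitoes released per recording session.
COHORT_SIZE = 200


class FunctionalArea(str, Enum):
    """Zones of a bed net under characteristically different mosquito pressure.

    FA1 is the roof; FA2-low the bottom 0-30 cm of the sides; FA2-high the
    30-60 cm band; FA3 the upper two-thirds of the sides.  Roof holes are
    always scored as FA1 (a deliberately cautious convention, since sleepers
    move and nets hold more than one person).
    """

    FA1 = "FA1"
    FA2_LOW = "FA2_LOW"
    FA2_HIGH = "FA2_HIGH"
    FA3 = "FA3"

    @property
    def orientation(self) -> str:
        """``"roof"`` for FA1, ``"side"`` otherwise."""
        return "roof" if self is FunctionalArea.FA1 else "side"

    @classmethod
    def from_height(cls, surface: str, bottom_height_mm: float = 0.0) -> "FunctionalArea":
        """Map a (surface, height band) description to a functional area.

        Side holes map by the height of their bottom edge above the net's
        lower hem: [0, 300) mm -> FA2-low, [300, 600) mm -> FA2-high, 600 mm
        and above -> FA3.  Any roof hole is FA1.
        """
        if surface == "roof":
            return cls.FA1
        if surface != "side":
            raise ValueError(f"surface must be 'roof' or 'side', got {surface!r}")
        if bottom_height_mm < 300.0:
            return cls.FA2_LOW
        if bottom_height_mm < 600.0:
            return cls.FA2_HIGH
        return cls.FA3


class PassageLine(BaseModel):
    """Log-linear per-encounter passage model ``p = slope*ln(w_mm) + intercept``."""

    model_config = ConfigDict(frozen=True)
    slope: float = Field(gt=0)
    intercept: float

    @property
    def zero_crossing_mm(self) -> float:
        """Width at which the unclamped line crosses zero probability."""
        return math.exp(-self.intercept / self.slope)


class SpeciesParameters(BaseModel):
    """All constants of the appearance -> encounter -> passage model."""

    model_config = ConfigDict(frozen=True)

    appearances_per_mosquito_hour: Dict[FunctionalArea, float] = Field(
        default={
            FunctionalArea.FA1: 72.3,
            FunctionalArea.FA2_LOW: 9.5,
            FunctionalArea.FA2_HIGH: 1.5,
            FunctionalArea.FA3: 0.3,
        }
    )
    #: Per-appearance encounter probability per unit of (perimeter_mm + area_mm2).
    encounter_coefficient: float = 9e-6
    passage_roof: PassageLine = PassageLine(slope=0.34, intercept=-0.55)
    passage_side: PassageLine = PassageLine(slope=0.30, intercept=-0.52)
    #: Sections at or below this width (mm) are impassable.
    impassable_width: float = 5.0
    #: Section length (mm) for the average-width procedure.
    section_length: float = 10.0
    #: Largest hole length/width (mm) meaningful per entry: the 30 cm
    #: sampling-unit size underpinning every rate in the model.
    max_entry_dimension: float = 300.0

    def passage_line(self, orientation: str) -> PassageLine:
        if orientation == "roof":
            return self.passage_roof
        if orientation == "side":
            return self.passage_side
        raise ValueError(f"orientation must be 'roof' or 'side', got {orientation!r}")

    def parameter_hash(self) -> str:
        """Stable short hash of the parameter values, for report provenance."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SpeciesParameters":
        """Load overrides from a YAML or JSON file (missing keys keep defaults)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        base = cls().model_dump()
        base.update(data)
        return cls.model_validate(base)


DEFAULT_PARAMETERS = SpeciesParameters()
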