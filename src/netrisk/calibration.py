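"""Recalibration of the per-encounter passage model from count data.

The passage model (``p = slope*ln(width) + intercept``, separate lines for
roof and side holes) was derived from laboratory encounter/passage counts
for *An. gambiae* on untreated netting.  Users working with other vector
species or net materials can refit it from their own observation tables:
one row per hole (width, optional length, location, shape, number of
encounters, number of passages).

Fits are ordinary least squares of the per-row passage proportion on the
chosen predictor (width, ln(width), length, perimeter or area), unweighted
by default; encounter-weighted least squares is available because row
encounter counts can differ by an order of magnitude.  The regression
machinery is statsmodels OLS/WLS behind this module's surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PassageObservation",
    "CalibrationFit",
    "PassageCalibration",
    "fit_passage_model",
    "compare_predictors",
    "read_observations",
    "reference_observations",
    "PREDICTORS",
]

PREDICTORS = ("width", "ln_width", "length", "perimeter", "area")

Location = Literal["roof", "side"]


class PassageObservation(BaseModel):
    """One hole's encounter/passage tally.

    ``width_mm`` is the hole width (diameter for round holes, average width
    for triangular ones).  Counts may be fractional to allow exact-proportion
    synthetic rows.
    """

    model_config = ConfigDict(frozen=True)

    width_mm: float = Field(gt=0)
    length_mm: Optional[float] = Field(default=None, gt=0)
    location: Location
    shape: Literal["rectangle", "circle", "triangle"] = "rectangle"
    encounters: float = Field(gt=0)
    passages: float = Field(ge=0)

    @model_validator(mode="after")
    def _counts(self) -> "PassageObservation":
        if self.passages > self.encounters:
            raise ValueError("passages cannot exceed encounters")
        return self

    @property
    def proportion(self) -> float:
        return self.passages / self.encounters

    def predictor_value(self, predictor: str) -> Optional[float]:
        """Value of ``predictor`` for this row, or None if not derivable."""
        w, L = self.width_mm, self.length_mm
        if predictor == "width":
            return w
        if predictor == "ln_width":
            return math.log(w)
        if predictor == "length":
            return L
        if self.shape == "circle":
            if predictor == "perimeter":
                return math.pi * w
            if predictor == "area":
                return math.pi * w * w / 4.0
        if self.shape == "rectangle" and L is not None:
            if predictor == "perimeter":
                return 2.0 * (L + w)
            if predictor == "area":
                return L * w
        return None


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted passage line for one location and predictor."""

    location: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n_rows: int
    slope_se: float
    intercept_se: float
    weighted: bool

    def predict(self, predictor_value: float) -> float:
        return self.slope * predictor_value + self.intercept


class PassageCalibration:
    """statsmodels-style calibration model over a set of observations.

    ``PassageCalibration(obs, "side").fit("ln_width")`` returns a
    :class:`CalibrationFit`; :meth:`fit_all` ranks every derivable
    predictor by R^2.
    """

    def __init__(
        self,
        observations: Sequence[PassageObservation],
        location: Location,
        weighted: bool = False,
    ):
        self.observations = [o for o in observations if o.location == location]
        self.location = location
        self.weighted = weighted
        if not self.observations:
            raise ValueError(f"no observations for location {location!r}")

    def fit(self, predictor: str = "ln_width") -> CalibrationFit:
        if predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        rows = [
            (o.predictor_value(predictor), o.proportion, o.encounters)
            for o in self.observations
        ]
        rows = [r for r in rows if r[0] is not None]
        x = np.array([r[0] for r in rows])
        if len(rows) < 3:
            raise ValueError(f"need >= 3 rows with a {predictor!r} value")
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate design: {predictor!r} is constant")
        y = np.array([r[1] for r in rows])
        X = sm.add_constant(x)
        if self.weighted:
            res = sm.WLS(y, X, weights=np.array([r[2] for r in rows])).fit()
        else:
            res = sm.OLS(y, X).fit()
        return CalibrationFit(
            location=self.location,
            predictor=predictor,
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            r_squared=float(res.rsquared),
            n_rows=len(rows),
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            weighted=self.weighted,
        )

    def fit_all(self) -> List[CalibrationFit]:
        """Fit every derivable predictor, ranked by descending R^2."""
        fits = []
        for predictor in PREDICTORS:
            try:
                fits.append(self.fit(predictor))
            except ValueError:
                continue
        if not fits:
            raise ValueError("no predictor is derivable from these observations")
        return sorted(fits, key=lambda f: f.r_squared, reverse=True)


def fit_passage_model(
    observations: Sequence[PassageObservation],
    location: Location,
    predictor: str = "ln_width",
    weighted: bool = False,
) -> CalibrationFit:
    """OLS fit of per-row passage proportion on ``predictor`` for ``location``."""
    return PassageCalibration(observations, location, weighted).fit(predictor)


def compare_predictors(
    observations: Sequence[PassageObservation],
    location: Location,
    weighted: bool = False,
) -> List[CalibrationFit]:
    """Rank candidate predictors of passage probability by R^2."""
    return PassageCalibration(observations, location, weighted).fit_all()


def read_observations(path: Union[str, Path]) -> List[PassageObservation]:
    """Read an observation table from CSV.

    Expected header: ``width_mm,length_mm,location,shape,encounters,passages``
    (``length_mm`` may be blank).
    """
    df = pd.read_csv(path)
    required = {"width_mm", "location", "shape", "encounters", "passages"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    obs = []
    for i, row in df.iterrows():
        data = row.to_dict()
        if "length_mm" in data and pd.isna(data["length_mm"]):
            data["length_mm"] = None
        try:
            obs.append(PassageObservation.model_validate(data))
        except Exception as exc:
            raise ValueError(f"invalid observation on row {i + 2}: {exc}") from exc
    return obs


def reference_observations() -> List[PassageObservation]:
    """The packaged *An. gambiae* laboratory passage table.

    Hand-transcribed from the published table; the transcription should be
    verified against the typeset original before quantitative reuse (see the
    methods note).  Triangle rows carry their computed average width.
    """
    with resources.as_file(
        resources.files("netrisk.data") / "passage_observations_gambiae.csv"
    ) as p:
        return read_observations(p)
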