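"""Inventory reading and report writing.

A *hole inventory* describes a damaged net, one record per hole.  JSON is
canonical (``{"holes": [...]}`` or a bare list); CSV is equivalent with one
hole per line.  Each record names its functional area — either directly
(``fa: FA1|FA2_LOW|FA2_HIGH|FA3``) or as ``surface: roof|side`` plus, for
sides, ``bottom_height_mm`` — and exactly one geometric description: a
tagged shape (rectangle/circle/ellipse/triangle/polygon) with dimensions in
mm, or pre-measured ``perimeter_mm``/``area_mm2``/``avg_width_mm``.
Dimension keys with a ``_cm``/``_cm2`` suffix are accepted and converted.

Reading normalizes holes (metrics computed, >300 mm rectangles split) and
validates strictly, reporting the offending record on error.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .geometry import Measured, shape_from_dict
from .model import Hole, NetAssessmentResults, normalize_holes
from .params import DEFAULT_PARAMETERS, FunctionalArea, SpeciesParameters

__all__ = [
    "InventoryError",
    "InventoryRecord",
    "read_inventory",
    "holes_from_records",
    "write_report",
    "read_report",
    "inventory_json_schema",
]

_DIM_KEYS = (
    "length_mm", "width_mm", "diameter_mm", "major_mm", "minor_mm", "base_mm",
    "perimeter_mm", "area_mm2", "avg_width_mm",
)
_MEASURED_KEYS = ("perimeter_mm", "area_mm2", "avg_width_mm")


class InventoryError(ValueError):
    """Invalid inventory file or record."""


class InventoryRecord(BaseModel):
    """One validated inventory line (before geometry is computed)."""

    model_config = ConfigDict(extra="allow")

    hole_id: Optional[Union[str, int]] = None
    fa: Optional[str] = None
    surface: Optional[str] = None
    bottom_height_mm: Optional[float] = None
    shape: Optional[str] = None

    @model_validator(mode="after")
    def _check_location(self) -> "InventoryRecord":
        if self.fa is None and self.surface is None:
            raise ValueError("record needs 'fa' or 'surface'")
        if self.fa is not None:
            try:
                FunctionalArea(self.fa)
            except ValueError:
                raise ValueError(
                    f"unknown FA {self.fa!r}; expected one of "
                    f"{[f.value for f in FunctionalArea]}"
                )
        return self

    def functional_area(self) -> FunctionalArea:
        if self.fa is not None:
            return FunctionalArea(self.fa)
        return FunctionalArea.from_height(self.surface, self.bottom_height_mm or 0.0)


def _convert_cm(data: dict) -> dict:
    """Convert ``*_cm`` / ``*_cm2`` keys to their mm equivalents."""
    out = {}
    for key, value in data.items():
        if value is None:
            out[key] = value
        elif key.endswith("_cm2"):
            out[key[:-4] + "_mm2"] = float(value) * 100.0
        elif key.endswith("_cm"):
            out[key[:-3] + "_mm"] = float(value) * 10.0
        else:
            out[key] = value
    return out


def _record_to_hole(data: dict, index: int, params: SpeciesParameters) -> Hole:
    data = _convert_cm({k: v for k, v in data.items() if v is not None and v != ""})
    try:
        record = InventoryRecord.model_validate(data)
    except ValidationError as exc:
        raise InventoryError(f"record {index}: {exc.errors()[0]['msg']}") from exc

    shape_fields = {k: data[k] for k in _DIM_KEYS if k in data}
    has_measured = any(k in data for k in _MEASURED_KEYS)
    has_shape = record.shape is not None
    if has_shape and has_measured:
        raise InventoryError(f"record {index}: give either a shape or measured metrics, not both")
    if not has_shape and not has_measured:
        raise InventoryError(f"record {index}: no shape tag and no measured metrics")

    try:
        if has_shape:
            payload = {"shape": record.shape, **shape_fields}
            if record.shape == "polygon":
                payload["vertices_mm"] = data.get("vertices_mm")
                for k in _DIM_KEYS:
                    payload.pop(k, None)
            shape = shape_from_dict(payload)
        else:
            missing = [k for k in _MEASURED_KEYS if k not in data]
            if missing:
                raise InventoryError(
                    f"record {index}: measured hole missing {missing}"
                )
            shape = Measured(
                perimeter_mm=data["perimeter_mm"],
                area_mm2=data["area_mm2"],
                avg_width_mm=data["avg_width_mm"],
                length_mm=data.get("length_mm"),
            )
    except InventoryError:
        raise
    except (ValidationError, ValueError) as exc:
        raise InventoryError(f"record {index}: {exc}") from exc

    hole_id = str(record.hole_id) if record.hole_id is not None else f"h{index}"
    return Hole.from_shape(hole_id, record.functional_area(), shape, params)


def holes_from_records(
    records: Sequence[dict],
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    normalize: bool = True,
    strict: bool = False,
) -> List[Hole]:
    """Validate raw record dicts into normalized :class:`Hole` objects."""
    holes = [_record_to_hole(dict(r), i + 1, params) for i, r in enumerate(records)]
    return normalize_holes(holes, params, strict) if normalize else holes


def read_inventory(
    path: Union[str, Path],
    format: Optional[str] = None,
    params: SpeciesParameters = DEFAULT_PARAMETERS,
    normalize: bool = True,
    strict: bool = False,
) -> List[Hole]:
    """Read a hole inventory from a JSON or CSV file."""
    path = Path(path)
    if not path.exists():
        raise InventoryError(f"inventory file not found: {path}")
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InventoryError(f"{path}: invalid JSON ({exc})") from exc
        records = payload.get("holes", []) if isinstance(payload, dict) else payload
        if not isinstance(records, list):
            raise InventoryError(f"{path}: expected a list of hole records")
    elif fmt == "csv":
        with path.open(newline="") as fh:
            records = [
                {k: v for k, v in row.items() if v not in (None, "")}
                for row in csv.DictReader(fh)
            ]
        for rec in records:
            for key in list(rec):
                if key.endswith(("_mm", "_mm2", "_cm", "_cm2")) or key == "bottom_height_mm":
                    rec[key] = float(rec[key])
    else:
        raise InventoryError(f"unknown inventory format {fmt!r}")
    return holes_from_records(records, params, normalize, strict)


def write_report(results: NetAssessmentResults, path: Union[str, Path]) -> None:
    """Write an assessment report as JSON (full precision)."""
    Path(path).write_text(json.dumps(results.to_dict(), indent=2) + "\n")


def read_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def inventory_json_schema() -> dict:
    """JSON schema of a single inventory record (also shipped in package data)."""
    from importlib import resources

    return json.loads(
        (resources.files("netrisk.data") / "inventory.schema.json").read_text()
    )
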