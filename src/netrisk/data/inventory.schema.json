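{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "netrisk hole inventory record",
  "description": "One hole on a damaged bed net. Give the location as 'fa' or as 'surface' (+ 'bottom_height_mm' for side holes), and exactly one geometric description: a tagged shape with dimensions in mm, or measured perimeter/area/average width. Keys suffixed _cm/_cm2 are accepted and converted to mm.",
  "type": "object",
  "properties": {
    "hole_id": {"type": ["string", "integer"]},
    "fa": {"enum": ["FA1", "FA2_LOW", "FA2_HIGH", "FA3"]},
    "surface": {"enum": ["roof", "side"]},
    "bottom_height_mm": {"type": "number", "minimum": 0},
    "shape": {"enum": ["rectangle", "circle", "ellipse", "triangle", "polygon"]},
    "length_mm": {"type": "number", "exclusiveMinimum": 0},
    "width_mm": {"type": "number", "exclusiveMinimum": 0},
    "diameter_mm": {"type": "number", "exclusiveMinimum": 0},
    "major_mm": {"type": "number", "exclusiveMinimum": 0},
    "minor_mm": {"type": "number", "exclusiveMinimum": 0},
    "base_mm": {"type": "number", "exclusiveMinimum": 0},
    "vertices_mm": {
      "type": "array",
      "minItems": 3,
      "items": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
    },
    "perimeter_mm": {"type": "number", "minimum": 0},
    "area_mm2": {"type": "number", "minimum": 0},
    "avg_width_mm": {"type": "number", "minimum": 0}
  },
  "anyOf": [
    {"required": ["fa"]},
    {"required": ["surface"]}
  ]
}
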