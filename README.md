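# netrisk

**Mosquito entry-risk assessment for physically damaged bed nets.**

Insecticide-treated bed nets accumulate rips and tears in use, and the
field-standard damage score — the WHOPES proportionate hole index (pHI) —
counts and sizes holes but discards *where* they are.  For *Anopheles
gambiae* that matters enormously: mosquito pressure on the net roof is
roughly 250 times that on the upper sides, and roof holes are ~20 % more
passable than equally wide side holes.  `netrisk` implements a behavioural
entry-risk model that turns a net's hole inventory (location, shape, size)
into an expected number of mosquito entries per hour, for programme
decisions about net serviceability and replacement.

## The model

For each hole, under the *one-mosquito-constantly-present* convention (one
mosquito always attacking, each entrant instantly replaced),

```
entries/h = A_FA x [9e-6 (P + A)] x clamp(b ln w + a, 0, 1)
```

where `A_FA` is the functional area's hourly appearance rate per mosquito
per 30 x 30 cm (FA1 roof 72.3, FA2-low 9.5, FA2-high 1.5, FA3 0.3), `P` and
`A` are the hole's perimeter (mm) and area (mm²), and the passage term is
log-linear in the hole's average passable width `w` (mm): `0.34 ln w −
0.55` on the roof, `0.30 ln w − 0.52` on the sides.  Widths of 5 mm or less
are impassable.  Hole metrics for rectangles, circles, ellipses, triangles
and traced irregular outlines — including the 1-cm average-width sectioning
procedure and convex-hull effective perimeters — are computed by the
`geometry` module.  See `docs/methods.md` for the full account.

## Worked example

A typically damaged net: three 300 x 70 mm tears in each of FA2-low and
FA2-high, five in FA3, and three small 30 x 30 mm squares on the roof.

```python
from netrisk import EntryRiskModel
from netrisk.scenarios import fig9_holes

results = EntryRiskModel(fig9_holes()).fit()
print(results.summary())
```

or equivalently `netrisk scenario fig9`:

```
FA1           1.21 entries/h  ( 19%)
FA2_LOW       4.21 entries/h  ( 67%)
FA2_HIGH      0.66 entries/h  ( 11%)
FA3           0.22 entries/h  (  4%)
TOTAL         6.30 entries/h  (roof 19% / sides 81%)
```

The net admits ~6.3 mosquitoes per hour per attacking mosquito; 81 % of the
risk comes from the side tears, but the three small roof squares — about
1 % of the hole area — would still admit ~1.2/h on their own.  Scale to a
night with ten attacking mosquitoes via `results.scaled(10, 8)`.

Other entry points:

```
$ netrisk measure --shape ellipse --major 120 --minor 8
perimeter: 267.2 mm
area:      754.0 mm2
avg width: 7.0 mm

$ netrisk equivalent --reference-diameter 25 --reference-fa FA1 --target-fa FA2_HIGH
reference: 25.0 mm circle in FA1 -> 0.2017 entries/h
equivalent diameter in FA2_HIGH: 138.8 mm (13.9 cm)
```

— a 2.5 cm roof hole carries the same risk as a 13.9 cm hole lower on the
side, or a ~31 cm hole on the upper sides.  `netrisk assess -i net.json`
scores your own inventory (JSON or CSV; schema in
`src/netrisk/data/inventory.schema.json`), `netrisk phi` computes the
WHOPES pHI beside the modelled risk, and `netrisk simulate` cross-checks
the deterministic rates with a stochastic appearance/encounter/passage
simulation.  The passage model can be refitted for other species from
encounter/passage count tables with `netrisk.calibration`.

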