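# Methods

## The model

`netrisk` estimates the rate at which host-seeking female *Anopheles
gambiae* enter a physically damaged bed net, from an inventory of the net's
holes.  Entry through a hole is decomposed into three observable steps, each
with its own predictor:

```
entries/h = (appearances/h) x P(encounter | appearance) x P(passage | encounter)
```

* **Appearance** — a mosquito flying within ~1-1.5 cm of a 30 cm x 30 cm
  patch of net surface.  Mosquito pressure is wildly uneven over the net:
  the roof (functional area FA1) receives by far the most attention,
  followed by the bottom 30 cm of the sides (FA2-low), the 30-60 cm band
  (FA2-high) and the upper two-thirds (FA3).  The default per-mosquito
  hourly appearance rates are 72.3 / 9.5 / 1.5 / 0.3 for
  FA1 / FA2-low / FA2-high / FA3, derived from laboratory video counts of a
  200-mosquito cohort (14,450 / 1,900 / 300 / 60 appearances per hour, an
  activity ratio of roughly 250:33:5:1 per unit area).
* **Encounter** — impinging on the hole during an appearance, modelled as
  `9e-6 x (perimeter_mm + area_mm2)`, clamped to [0, 1].  Perimeter captures
  skimming ("bouncing") flight along the surface, area captures approaches
  through the plane of the net; their sum predicts encounters well across
  hole shapes and extrapolates sensibly (a hole the size of the 30 cm
  sampling unit yields probability ~0.82, where 1.0 is the ideal).
* **Passage** — traversing the hole once encountered, log-linear in the
  hole's average passable width `w` (mm): `0.34 ln w - 0.55` for roof holes,
  `0.30 ln w - 0.52` for side holes, clamped to [0, 1].  Narrow holes are
  disproportionately impassable (the "edge effect": collisions of wings and
  appendages with hole edges deflect the mosquito), and roof holes are
  ~20 % more passable than side holes of the same width — mosquitoes drop
  through them with gravity, inside the rising host-odour plume.  Both lines
  cross zero near 5 mm, so widths of 5 mm or less are impassable; widths
  above ~95 mm (roof) / ~175 mm (side) are fully passable.

All rates follow the *one-mosquito-constantly-present* convention: exactly
one mosquito attacks the net at all times, every entrant instantly replaced.
Risks therefore scale linearly in attacking-mosquito number and exposure
time (`results.scaled(n, hours)`).

### Assumptions and scope

The calibration is laboratory *An. gambiae* on untreated netting in still
air.  The model ignores net exit (the net is treated as a perfect sink — a
deliberately conservative choice for a protection estimate), insecticide
effects (a fully effective treatment may cut entry by ~70 % or more via
reduced activity alone), drafts that disturb the odour plume, and net
sagging.  Every roof hole is scored as FA1 regardless of position, again
conservatively.  Parameters for other species or conditions are
configuration (`SpeciesParameters.from_file`), not fitted by this package;
only the passage line is refittable from count data (`calibration`).

## Hole geometry

The model consumes three numbers per hole: perimeter (mm), area (mm²) and
average passable width (mm).

* Rectangles, circles and isosceles triangles use closed forms.  A circle's
  width is its diameter.
* Ellipses use the exact area `pi*a*b` and the quadratic-mean perimeter
  `2*pi*sqrt((a^2+b^2)/2)` (semi-axes `a >= b`).  Against an arc-length
  quadrature oracle the approximation is within 5 % for aspect ratios up to
  3 — strictly, 5.12 % exactly at aspect 3, which is how the property tests
  bound it.  Most real net holes are elliptical with aspect <= 3.  For very
  narrow ellipses an optional fallback estimates the perimeter as twice the
  major axis; it is off by default to keep the estimate continuous in the
  axes.
* **Average width** follows the field sectioning procedure: tile the
  longest axis into 10 mm sections (final partial section kept, midpoints at
  5, 15, 25, ... mm), evaluate the transverse width at each section
  midpoint, and average the midpoints *strictly greater than* 5 mm; 0 if
  none qualifies.  The comparison uses unrounded widths: a section of true
  width 5.29 mm counts, and the worked narrow-ellipse example (120 x 8 mm →
  7 mm) reproduces either way.  Note that grid-measured figures for wide
  holes can differ from the analytic profile (a 120 x 50 mm ellipse sections
  to 39.6 mm analytically); the procedure, not any one drawing, is the
  specification.
* **Irregular outlines** (traced polygons) get the shoelace area and an
  *effective perimeter*: the smaller of the raw boundary length and the
  convex-hull perimeter.  A crenellated tear has an arbitrarily long raw
  boundary that would absurdly inflate the encounter term; the hull bounds
  what a surface-skimming mosquito can meet.  Both values are retained in
  the metrics record.  The width-profile axis is the direction of maximal
  vertex-to-vertex extent (rotating calipers); widths are measured
  perpendicular to it, summing across lobes of concave outlines.  This axis
  choice is a determinization — any convention parallel to the hole's
  elongation gives equivalent results for realistic tears.

### Entry rules

Because every rate is defined per 30 cm x 30 cm sampling unit, no single
entry may exceed 300 mm in length or width.  Rectangles longer than 300 mm
are split into `ceil(L/300)` equal fragments, each keeping its own full
perimeter (the shared cut edges are double-counted, mirroring row-wise entry
of a long tear in a per-unit assessment; the published example splits a
400 mm hole into two rows).  Equal-length splitting is this package's
determinization of that rule.  Measured records with a known length split
the same way via a rectangle-equivalent.  Other oversize shapes cannot be
split mechanically; in strict mode they error, by default they are kept with
a warning — necessarily so, since the published equal-risk scenario itself
contains a 307 mm round hole.  A helper (`split_at_fa_boundaries`)
apportions tall side tears at the 300/600 mm height boundaries, half-open
bands, each fragment assessed with its own metrics.

## Equivalent diameters

`equivalent_diameter(rate, fa)` inverts the model: the diameter of a round
hole in a given FA carrying a given hourly risk.  The rate is continuous and
strictly increasing in diameter (above the impassability threshold the
passage term rises, and once it clamps at 1 the encounter term keeps
growing), so the root is unique; it is bracketed and solved by Brent's
method to 0.001 mm.  The solver deliberately ignores the 300 mm cap — its
output is an abstract size equating risks, e.g. a 2.5 cm roof hole equals a
~6.3 cm hole in FA2-low, ~13.9 cm in FA2-high and ~30.6 cm in FA3 (the FA3
solution lies in the clamped regime, where only the encounter term moves).

## The pHI baseline

The WHOPES proportionate hole index bins holes by template "diameter"
(longest extent, whatever the true shape) into four classes — smaller than
thumb [0.5, 2) cm, thumb-fist [2, 10) cm, fist-head [10, 25) cm, larger
than head >= 25 cm, boundaries assigned upward, holes under 0.5 cm ignored —
and sums counts times per-class weights.  Thresholds 64 (good/acceptable)
and 642 (acceptable/too torn) are inclusive on the acceptable side.  The
default weights (1, 23, 196, 578) are WHO-guidance area-derived values and
are configuration; only the classes and thresholds are behaviourally
anchored.  The index ignores hole location, which is the substantive
critique: three 3 x 3 cm roof holes (pHI 69) out-risk a 25 cm FA3 hole
(pHI 578) by an order of magnitude in modelled entries — the discordance is
asserted as a test.

## Calibration refits

`PassageCalibration` refits the passage line from observation tables (one
row per hole: width, optional length, roof/side, shape, #encounters,
#passages) by OLS of the per-row passage proportion on a chosen predictor
(width, ln width, length, perimeter, area), via statsmodels.  Unweighted
OLS is the default; because row encounter counts span an order of
magnitude, encounter-weighted WLS is available (and is the variant invariant
to splitting a row's counts in half).  On data simulated from the ln-width
truth, ln(width) ranks first by R² and slope/intercept estimates are
unbiased (checked by replicate Monte-Carlo at 50-5000 encounters/row).

A hand-transcribed copy of the original laboratory table ships in
`netrisk/data/passage_observations_gambiae.csv` (59 rows).  The
transcription was recovered from a degraded rendering of the printed table
and should be verified against the typeset original; as a strong internal
check, refitting it reproduces the published regressions to the third
decimal (side ln-width: slope 0.302, intercept −0.519, R² 0.927 vs printed
0.302 / −0.52 / 0.9256; roof: 0.343 / −0.547, R² 0.862 vs 0.343 / 0.8621).
One side row (20 x 32 mm) shows 34/87 = 0.39 where the printed proportion
reads 0.43; the counts were kept as parsed.  The exact published fitting
protocol (pooling, weighting) is unstated, so printed R² values are a soft
check only.

## Synthetic data and the stochastic oracle

`GeneratorSpec`/`generate_inventory` produce reproducible random
inventories covering all FAs and shape variants.  Hole widths are
log-uniform on 1-300 mm — real damage inventories are dominated by small
holes, with large tears present but rare — with aspect ratios 1-6 for
elongation; sub-threshold holes and >300 mm tears are included so
normalization paths are exercised.  Generated polygons are star-shaped
radial blobs (an ellipse of the requested elongation modulated by smooth
low-order harmonics), rescaled to the target area; star-shapedness
guarantees simple outlines, and the pre-noise ellipse is retained for
oracle comparisons.  What the generator does *not* emulate: spatial
clustering of damage (seam failures), hole-shape correlations with cause,
or growth of holes over time — passing tests say the model arithmetic and
plumbing are right under realistic marginals, not that any particular field
damage distribution is represented.

`simulate_entries` realizes the model stochastically: per hole, appearances
over the exposure are Poisson with the FA's hourly rate, thinned by a
Bernoulli encounter and then a Bernoulli passage.  The thinned count is
again Poisson with mean equal to the deterministic `rate x hours x
mosquitoes`, so the simulator is a genuine distributional oracle: tests
require the simulated hourly mean over 10⁴ replicate hours to fall within 3
standard errors of the deterministic rate.  Appearances are modelled as a
homogeneous process; observed activity fluctuates within sessions, but only
the hourly expectation enters the risk model.

## Numerical choices

* All metrics are kept at full float precision; rounding to mm, 2-decimal
  rates or whole-percent shares happens only at presentation time.
* Probabilities are clamped to [0, 1] at the point of use; the encounter
  clamp is defensive (max in-range value ~0.82).
* The passage lines use ln(width in mm); their zero crossings
  (`exp(-intercept/slope)` = 5.04 mm roof, 5.65 mm side) are consistent with
  the 5 mm impassability threshold.
* Rectangle records entered with width > length are silently reordered.
* Degenerate inputs: empty inventories assess to zero; profiles with no
  passable section return width 0; collinear vertex sets and
  self-intersecting outlines are rejected as invalid shapes.
* Report JSON reserves a `confidence_limits` field but computes none: the
  variance/covariance inputs required to propagate 95 % limits are not
  published.

## Problem sizes

Everything the package computes is desk-scale: the worked scenarios are
14-hole inventories evaluated in microseconds, the Monte-Carlo validation
uses 10⁴ replicate hours (~10⁵ Poisson/binomial draws), and calibration
replicates use 8-row tables at up to 5,000 encounters per row.

## Known limitations

* The FA map and all rates are specific to *An. gambiae* on a rectangular
  net; species with different net-surface distributions need their own
  appearance rates (the package accepts them as config but cannot derive
  them).
* Encounter-model refitting is out of scope (per-appearance encounter raw
  data are not available), as are GLM/logistic passage alternatives.
* The pHI weights are external configuration; pHI *values* are therefore
  configuration-dependent, and only class structure and thresholds are
  intrinsic.
* Measured-record splitting uses a rectangle-equivalent perimeter, an
  approximation adequate for the elongated tears the rule exists for.
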