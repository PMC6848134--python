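# Methods

## The model

The susceptibility of occurrence of a carbonate factory at a grid cell is a
convex combination of fuzzy membership values over four environmental
parameters,

    F = a f(z) + b f(SST) + c f(SSS) + d f(P),   a + b + c + d = 1,

evaluated on co-registered lat–lon rasters and masked wherever carbonate
production is inhibited. The model assumes (i) each factory occupies a
coherent environmental envelope describable by unimodal (or one-sided)
membership functions of sea-surface parameters; (ii) seasonality matters —
a warm-season *production* requirement and a cool-season *persistence*
requirement are distinct constraints; (iii) terrigenous input and water
depth act as hard constraints rather than graded ones; and (iv) factories
compete for cells, with the heterozoan-C factory behaving as an
opportunistic background that is overwhelmed wherever any other factory
develops.

Presence is declared where F strictly exceeds a per-factory final
threshold. Where several non-background factories clear their thresholds,
the cell goes to the one with the largest margin F − threshold (ties broken
by the fixed order biochemical > photozoan-T > photo-C). This margin rule
matters: with the default parameterization the *occurrence* regions of the
factories genuinely overlap in parts of (SST_summer, SST_winter) space —
e.g. a 28 °C summer with an 18 °C winter clears both the photozoan-T and
photo-C thresholds, and a hypersaline-gulf cell clears both the biochemical
and photozoan-T thresholds — and it is the combination step that renders
the final map exclusive. The background factory is assigned only to cells
no other factory claims, where its own threshold is cleared and the
seasonal-mean absorption reaches its floor (default 0.01 m⁻¹; with the
default near-Gaussian spread and a 0.5 threshold the implied floor is
≈0.015 m⁻¹, so the explicit rule is kept separate and configurable).

## Membership forms and calibration

The two bell forms attain 1 at the mid-point and cross ½ at
MP ± √(ln 2⁄S) (Gaussian) and MP ± 1/√S (near-Gaussian); matched to share
their ½-crossings, the near-Gaussian has heavier tails *outside* the
crossings and the Gaussian dominates inside them. The large sigmoid is
monotone with f(MP) = ½ exactly; it is undefined for x ≤ 0 and such inputs
return 0 (total inhibition) — the form is used only for the biochemical
factory's SST, where non-positive temperatures carry no affinity anyway.

Calibration proceeds from footprints: environmental values are pooled over
the cells of each observed factory, summarized per season by percentiles
with linear interpolation between order statistics (the estimator is a
documented choice; whisker levels are p1/p99 for SST and salinity class,
p5/p95 for absorption), and converted to thresholds — production from the
warm season's lower whisker, persistence from the cool season's, the upper
threshold from the larger of the seasons' upper whiskers. The mid-point is
the mean of the lower and upper thresholds, two lower thresholds being
averaged first; with a single threshold the mode is used instead. Spreads
solve f(threshold) = ½ in closed form: S = ln 2/(x−MP)² (Gaussian),
S = 1/(x−MP)² (near-Gaussian); sigmoid spreads invert
S = −ln(1/f − 1)/ln(x/MP) from a reference point.

The warm-temperate (photo-C) SST mid-points (25.25 production, 12.325
persistence) and the biochemical sigmoid spread (58) ship as fixed defaults
rather than calibration outputs; the published account does not derive
them, and the calibration module makes no attempt to reconstruct an
unreported procedure. The bathymetry membership is the indicator of the
factory's depth interval (1 inside, masked outside): the graded depth
curves this replaces were reported to control no distributional trend, and
their weight is small (0.03–0.10, set to 1 − (b + c + d) so each factory's
weights sum to 1 exactly).

## Default parameterization

| factory | SST | SSS (class) | P (m⁻¹) | weights a,b,c,d | threshold | depth |
|---|---|---|---|---|---|---|
| biochemical | sigmoid MP 30.5 S 58, warm season | near-Gauss MP 8 S 3, cool season | independent | .10 .45 .45 0 | 0.6 | 0–100 m |
| photozoan-T | Gauss MP 25.7 S 0.03, seasonal mean | Gauss MP 5 S 0.043 | Gauss MP 0.015 S 565 | .03 .64 .06 .27 | 0.7 | 0–100 m |
| photo-C | Gauss 25.25/0.025 (summer) × Gauss 12.325/0.0244 (winter) | Gauss MP 7 S 0.075 | Gauss MP 0.0203 S 2450 | .04 .62 .12 .22 | 0.5 | 0–200 m |
| heterozoan-C | independent | independent | near-Gauss MP 0.06 S 625 | .10 0 0 .90 | 0.5 | 0–200 m |

Seasonal rules not fixed by the parameterization itself are design
choices, overridable in the YAML config: biochemical SST uses the warm
season (the factory needs >30.5 °C during at least one season) and its
salinity the cool season (hypersalinity must hold year-round); photozoan-T
SST uses the seasonal mean, which places its ½-crossings at 20.9 and
30.5 °C and reproduces the warm-but-never-hot exclusion (seasonal mean
≈21 °C gives F ≈ 0.690 < 0.7, the model's southwestern-Australia case);
all remaining parameters use the seasonal mean. Note the single photozoan
Gaussian over the seasonal mean cannot also encode "never exceeds 24 °C"
for near-constant SST just below 24 — a corner of SST space with no real
ocean analogue. Salinity classes averaged across seasons stay fractional
(classes 5 and 6 feed the membership as 5.5); bins are left-closed except
the open-topped class 8 (≥37.5 psu), and sub-30 psu water clamps to class
1 with a logged warning rather than masking, since brackish inhibition is
already encoded in the membership functions.

Weighting by the analytic hierarchy process uses the standard Saaty
eigenvector method (power iteration to 1e−12) and random-index table; the
row/column rescaling that preserves reciprocity is a similarity transform,
so it preserves λmax while scaling the affected weight — the implementation
is checked against a dense eigendecomposition rather than any stronger
invariance.

## Evaluation

Both maps are expanded into four binary presence layers *from the
categorical assignment*; each matching layer contributes 25% to the cell's
accuracy and the global figure is the arithmetic mean over the evaluation
domain (default: 0–200 m shelf cells outside the high-terrigenous and
arctic masks). Deriving layers from categories (rather than from
pre-combination occurrence bits) keeps the metric symmetric, makes a map
score 100% against itself, and is stable under serialization, at the cost
of not crediting suppressed background presence. Anomalies are layer
mismatches, split into overestimation (predicted, not observed) and
underestimation per factory; their repartition is reported mechanically,
with no attempt to reproduce interpretive anomaly categories.

## The synthetic world

`synthetic_world.generate_env` builds, deterministically per seed, a
120×240-cell (1.5°) planet with two meridional continents: annual-mean SST
falls from 28 °C at the equator to −2 °C at the poles as cos²(lat) with a
seasonal amplitude growing from 1.5 to 10 °C; salinity has a subtropical
maximum near 37 psu and a marginal gulf at 39.5 psu whose warm season is
boosted 10 °C above the zonal profile (so gulf summers exceed 30.5 °C);
absorption is 0.012 m⁻¹ in the subtropical gyres, rising to 0.05 m⁻¹
poleward of ≈45°, with 0.08 m⁻¹ upwelling stripes (cooled by 3 °C) along
western continental margins between 12° and 40°; shelves ramp from 15 to
190 m over 7.5° of longitude; a river-mouth band is flagged "high"
terrigenous, mid-latitude inner-shelf fringes "low", and everything
poleward of 72° "arctic". Gaussian field noise (0.2 °C, 0.1 psu,
0.0015 m⁻¹) is truncated to physical ranges and the cool season is clamped
to never exceed the warm season. These values were chosen once as
field-realistic magnitudes for a coarse climatology.

The generator emulates structure, not dynamics: no currents, no real
coastlines, no within-platform topography, no remote-sensing artifacts.
Truth maps are produced by running the model itself under a designated
truth parameterization, so self-consistency tests demonstrate that the
pipeline is deterministic and internally coherent — they say nothing about
how well the niche functions fit the real ocean. Calibration-recovery
tests use dedicated synthetic footprints (`calibration_world`): uniform
samples placed so the generating percentiles sit exactly on the membership
½-crossings, which isolates the calibration chain from world geometry; on
2 500-cell footprints the chain recovers mid-points to well under 5% and
spreads to well under 20%.

## Numerical choices and limitations

Percentiles use linear interpolation between closest ranks. Resampling is
bilinear for continuous fields and nearest-neighbour for categorical ones;
identical lattices pass through bitwise. Presence uses a strict
inequality, so F exactly at the threshold is absence. Overlay results are
clamped to [0, 1] (a no-op given convex weights and bounded memberships,
kept as a guard). All randomness flows through explicit seeds; predictions
are reproducible byte-for-byte. Problem sizes in the shipped tests —
120×240 worlds, 2 500-cell footprints, 500×500 SST planes — keep every
check comfortably fast while leaving sampling error far inside the stated
tolerances.

The model predicts environmental susceptibility, not carbonate production
rates, biota or within-platform facies; carbonate chemistry terms (pCO₂,
alkalinity, saturation state) and hydrodynamics are outside its scope.
GeoTIFF IO is not provided; grids travel as CF-style NetCDF.
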