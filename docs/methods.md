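# Methods

This note records the model and procedure `sagehab` implements, the choices
made where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Study design and its assumptions

The analysis quantifies second-order habitat selection — the placement of
seasonal ranges within a region — for a sagebrush-obligate grouse from
presence-only location data. Its core assumptions:

- Used points (telemetry fixes, lek records) are informative about selection
  at a 1-km grain, and selection responds to landscape *context*, so every
  contextual covariate is summarized over a 5-km-radius circular buffer
  before entering the model.
- Available points have unknown use status. All evaluation is therefore
  one-sided: classification error is computed for the used class only, AUC
  is not used, and calibration compares expected vs observed *used* counts
  within quantile bins of predicted probability (Spearman's ρ over bins).
- Telemetry fixes are separated by several days, so serial autocorrelation
  of the movement process is ignored and every fix is retained.
- Site-to-site and year-to-year heterogeneity is absorbed by (a) stratifying
  the 1:1 availability draw by (site, year, season) and (b) entering year
  and site as categorical covariates.

## Seasons, sites, strata

Season windows are inclusive: breeding Apr 1 – May 31 (every lek record is
breeding regardless of date), summer Jun 1 – Aug 31, winter Nov 15 – Mar 15.
Dates in the two gaps are dropped with a logged count. A winter stratum is
labeled by the calendar year of its start, so one winter remains contiguous
in one stratum (a January 5 fix belongs to the winter that began the
preceding November). Sites are assigned by nearest site centroid, which is
identical to Voronoi-polygon membership; exact ties (a measure-zero event)
resolve to the lowest centroid index for determinism. Availability is drawn
uniformly within each site's Voronoi polygon clipped to the study region by
rejection sampling against the nearest-centroid rule.

## Covariate engineering

- **Focal proportions** — fraction of valid fine cells whose center lies
  within the (inclusive) radius; nodata cells leave both numerator and
  denominator; kernels truncate at the grid edge. Proportions over groups
  that partition the code table sum to 1 exactly.
- **Resampling to grain** — nearest fine-cell center to each coarse-cell
  center; exact halfway ties take the lower index (deterministic).
- **Line/point density** — clipped feature length (or point count) within
  the 5-km circle around each cell center, divided by circle area. Computed
  with exact geometric intersection; towers use point counts with the same
  radius, since the tool used for the original line layers does not apply to
  points.
- **VRM** — unit surface normals from Horn 3×3 slope/aspect; ruggedness of a
  (default 3×3) window is one minus the normalized resultant length of the
  normal vectors: 0 on any plane, growing with orientation dispersion.
- **Burned fraction** — area fraction of the 5-km circle covered by the
  union of fire perimeters from the 20 years *preceding* the query year (the
  one-year lag excludes the query year itself, since wildfires mostly burn
  in late summer).
- **Seasonal climate** — cellwise means of monthly normals over
  {Apr, May}, {Jun–Aug}, {Nov–Mar}.
- **Epoch lookup** — a location in year *y* uses the most recent cover epoch
  ≤ *y* (epochs 2001/2008/2010/2012 by default); years before the first
  epoch use the first.
- Slope is derived from the DEM by Horn's method when not supplied.

## Model and numerical choices

Random forest, 1,000 trees, minimum node size 1, mtry = 5, Gini impurity.
Year and site are one-hot encoded against an explicit registry from the
training data; mtry applies to the expanded columns, and the MDI of a
categorical predictor is the sum over its indicator columns. A category
unseen in training — the held-out site during spatial cross-validation —
encodes as an all-zero indicator vector, which is the intended
spatial-transfer semantics: prediction at a new site falls back on the
environmental predictors. MDI values are reported as scikit-learn's
normalized impurity-decrease shares (summing to 1 within a model); ranks and
across-fold mean/sd are unaffected by the normalization.

Predicted probabilities are clamped to [1/(2·B), 1 − 1/(2·B)] (B = number of
trees) before any ratio, so RSS denominators cannot be 0 or 1. The
classification threshold for confusion matrices is 0.5, natural under the
class-balanced design; balance is asserted at fit time. Calibration uses 10
quantile bins (deciles, the convention of the calibration method for
use-availability data); rows are ranked with a stable sort so heavy
probability ties still yield ten near-equal bins rather than merged ones,
and the expected used count per bin is the sum of predicted probabilities
(not bin midpoint × size). Folds are built over sites in sorted order, so
fold construction is independent of row order.

## RSS mapping

The reference pixel fixes every continuous predictor at its mean over valid
cells of the mapped region (the season's climate layers make those seasonal
means; the mapped region is the landscape extent, the synthetic analogue of
a statewide prediction) and the categorical year/site at the modal training
category — "mean value" is undefined for factors, and the mode is
deterministic and simple. Map cells take their geographic (Voronoi) site
label and the predictor set's map year. RSS at exactly the reference
composition is 1 to machine precision. The year-round mask assigns habitat
strictly above RSS = 1 in at least one season; a cell at exactly 1 in every
season is nonhabitat (the boundary is measure-zero after floating
arithmetic). Response curves span the predictor's observed range with all
other predictors at their means and pass through (mean, 1) by construction;
the reported curve is the fold-average.

## The synthetic landscape and what it does (not) show

The generator emulates the structure the analysis needs: a 36 × 36 km
landscape at 30-m fine grain; elevation as a smoothed Gaussian random field
(mean 2,000 m, amplitude 600 m, ~2-km autocorrelation); monthly temperature
decreasing with elevation at 6.5 °C/km and precipitation increasing
orographically, each plus smooth noise, so the covariate correlation of
mountain landscapes is present; land cover as per-class random fields
claimed sequentially at exact target shares (sagebrush types pooled to 35%),
re-perturbed per epoch; six soil fields; random transects for linear
infrastructure; random fire perimeters with years. Four population sites sit
on a jittered grid; territories (Voronoi cells) are therefore ~18 km across —
comfortably larger than the 5-km context buffer. That ratio matters: under
the stratified 1:1 design the only identifiable selection contrast is
*within* territories, and if territories are not much larger than the focal
buffer, the within-territory variance of context covariates collapses and no
method could recover the selection.

Used points are drawn over territory cells with probability ∝
exp(Σ βₚ xₚ) on the raw predictor scale; points are placed uniformly within
the chosen 1-km cell and dated uniformly within the season window. Leks sit
at each site's top-1% breeding-selection cells (one per site by default,
one record per year; the lek:telemetry mix is a config knob because the real
proportion is unknown). The demonstration coefficients make sagebrush
context the dominant effect in all seasons with season-dependent responses
to elevation, slope, maximum temperature, and soil depth, mirroring the
qualitative structure reported for the real system, with the weakest
signal-to-noise in winter.

What passing tests show: the estimator recovers *known* selection — with
selection on sagebrush only (β = +2), sagebrush ranks first by MDI in ≥ 9 of
10 seeds and the fold-and-seed-averaged response curve tracks
exp(β(x − x̄)) at Spearman ρ ≥ 0.9; a well-specified simulation calibrates
(mean validation ρ ≥ 0.8) while permuted labels sit at chance (0.5 ± 0.05);
and the pooling identities hold exactly. What they do not show: performance
under telemetry detection bias, movement autocorrelation, site-varying
selection, or misspecified availability — none of which the generator
simulates — nor the real study's error magnitudes, since the synthetic
selection is deliberately probabilistic and used/available points overlap
broadly in covariate space.

## Problem sizes

Default study conditions: 4 sites × 2 years × 3 seasons × 50 used points
per stratum (plus lek records), 1,296 mapped km². The bundled experiments
use a 60-m fine grain and, where many replicate fits are needed (the
ten-seed recovery experiment, the demonstration), 300-tree forests; the
calibration experiment uses the full 1,000 trees at ~2,000 used points per
class. These sizes were chosen so a complete run is a desk-scale job on one
CPU; all conclusions quoted above are computed at these sizes by
`scripts/acceptance.py` and the test suite, not imported from elsewhere.

## Known limitations

- No CRS handling or reprojection: all inputs must share one planar metric
  coordinate system (ASCII grid + GeoJSON I/O).
- Availability polygons are clipped to the rectangular landscape extent, the
  synthetic analogue of a statewide study region.
- MDI inherits the known bias of impurity importances toward high-cardinality
  predictors; within this pipeline all environmental predictors are
  continuous and comparably scaled, and the categorical year/site scores are
  indicator sums, so ranks are comparable but not unbiased in general.
- The fitted response curve is a single-slice partial dependence; far tails
  of a predictor's range combined with all-else-at-means can be
  extrapolation, which is why concordance with analytic truth is evaluated
  on the averaged curve.
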