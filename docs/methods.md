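# Methods

This note documents the models and procedures implemented in `forestmap`,
the parameter choices that matter, what the synthetic-scene generator does
and does not emulate, and the numerical conventions adopted where the
underlying method description leaves room.

## Plot signatures

Each field plot is represented by the raster covariates of a circular
footprint of 100 m² (radius √(100/π) ≈ 5.642 m) centred on the plot
coordinates. Continuous layers (the seven 10 m spectral bands, tree cover
density, composite quality) are summarised by the area-weighted mean: the
weight of a pixel is the fraction of the circle's area inside that pixel,
normalised to sum to 1. Categorical layers (forest type, canopy-loss year)
use the weighted mode — the category with the greatest summed weight — with
exact ties resolved to the lowest category code so results are independent
of enumeration order.

Circle–pixel overlap areas are computed by intersecting pixel squares with
a 256-vertex polygonal approximation of the circle (shapely). The polygon's
relative area deficit (~2.5e-4) cancels almost entirely in the weight
normalisation; measured against a 10⁶-sample stratified supersampling
oracle the per-pixel weight error stays below 1e-4, and refining the
polygon to 8192 vertices moves weights by less than 1e-5. The canopy-loss
layer is evaluated against its native 30 m grid with the same circle; no
resampling is applied.

A plot whose footprint leaves the raster, or touches nodata in any 10 m
layer, is flagged `excluded_offgrid`: in both cases the plot has no usable
raster support.

## Screening

Two screens partition the extracted plots, applied in this order:

* **Cloud/quality** — a plot is kept only when the footprint-weighted mean
  of the composite quality band strictly exceeds 4000. The aggregation to
  footprint level (rather than per pixel) is the least surprising reading
  of screening "observations"; the threshold itself is part of the method.
* **Canopy change** — a plot with recorded canopy-loss year
  ≥ min(2018, earliest measurement year − 1) is excluded (0 means no
  recorded loss and always passes). The forest-type and tree-cover layers
  have reference year 2018, hence the pivot.

Screening is a pure filter: kept and excluded plots partition the input and
no other field is altered.

## Validation split

Plots are sorted ascending by volume, with ties broken by plot id for
determinism, and 1-based positions 3, 6, 9, … are assigned to validation —
the one offset consistent with all fourteen published per-country counts
(validation = ⌊n/3⌋, e.g. 5 724 → 1 908). The split therefore depends only
on the set of plots, never on input order. The validation set is never used
to fit the feature scaler or the model; this is enforced by construction
(the scaler is computed inside `build_feature_matrix` from the mapping set
passed to it) and asserted in tests.

## Feature space and standardisation

Fixed column order: B2, B3, B4, B5, B8, B11, B12, TCD, FTY, then optionally
the 1 km grid easting and/or northing according to the processing area's
`location_mode` (`both_axes` for areas with in-area plots, `none` for
plot-free areas sourcing plots elsewhere, `northing_only` for the one
documented exception). Grid locations are plot coordinates floored to the
1 km cell origin. FTY enters as a single binary indicator (coniferous = 1,
broadleaved = 0); plots with a non-forest signature are excluded from
training since two remaining categories need one degree of freedom.

"All features have equal weights" is realised by standardising every
column to zero mean and unit variance on the mapping plots. This is a
deliberate interpretation: with raw units, grid coordinates (10⁶ m) would
dominate reflectances (10³) by three orders of magnitude in the Euclidean
distance, which cannot be what equal weighting means. A raw-units mode
(`scaling: "none"`) is provided for comparison; neither mode is claimed to
replicate any published map exactly. Zero-variance columns keep scale 1
with a warning.

## kNN prediction and uncertainty

Prediction at a query x is the inverse-distance-weighted mean of the k = 7
nearest training plots in standardized feature space, computed jointly for
all three responses from one shared neighbour set:

    ŷ = Σₗ wₗ yₗ,   wₗ ∝ 1 / max(dₗ, ε),   Σₗ wₗ = 1 .

The per-query uncertainty is the standard deviation of the neighbour
responses about the prediction with *unweighted* deviations and divisor k:

    s = sqrt( Σₗ (yₗ − ŷ)² / k ) .

This exact form (not k−1, not weighted) is kept for fidelity to the method
as published. Numerical conventions:

* **Zero distances** — dₗ is floored at ε = 1e-9 (standardized units), so a
  query coinciding with a training plot is dominated by it; weights are
  normalised after flooring.
* **Ties** — neighbour search is an exhaustive blocked scan; squared
  distances are plain sums of squared per-feature differences and ordering
  uses a stable sort, so ties at the k-th neighbour keep the lower
  training-row index. The test oracle implements the same rule, making
  oracle agreement exact rather than approximate.
* Predictions are convex combinations of neighbour responses, hence always
  within the neighbours' range and non-negative for non-negative responses.

Models serialise to a single `.npz` archive (features, responses, scaler,
parameters) and round-trip exactly.

## Map production

Features are evaluated at pixel centres, with location features from the
centre coordinate snapped to the 1 km grid. A pixel is predicted only when
all input layers are valid there, quality > 4000, and FTY marks forest.
The quality screen is applied at prediction time as well as training time —
such pixels are flagged nodata rather than predicted from contaminated
reflectance — and non-forest pixels are skipped entirely, since the output
semantics reserve 65534 for them.

Processing is windowed over row blocks; predictions are per-pixel
independent, so any window size reproduces the whole-array result bit for
bit (tested). Outputs are uint16 GeoTIFFs: 65535 nodata, 65534 non-forest,
0–65533 the physical value rounded half away from zero (a symmetric,
locale-independent rule; the rounding convention is not otherwise pinned
down) and clamped at 65533 — uncertainty layers included. Tiles live on a
500 km grid anchored so that E 3 900 000 / N 2 400 000 is a corner
(corner = ⌊(c − 400 km)/500 km⌋ · 500 km + 400 km; membership is half-open
so a corner belongs to the tile it names), and files are named
`{year}_{variable}_E{ee}_N{nn}.tif` with corners in units of 100 km. Full
500 km tiles (50 000² cells) are never materialised in tests; reduced
extents are written with correct georeferencing. GeoTIFF georeferencing and
nodata tags are written and read directly (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory with the EPSG code — default 3035, configurable —
and GDAL's nodata tag) via tifffile.

## Validation metrics

With y the reference and ŷ the prediction: RMSE = √(Σ(y−ŷ)²/n),
Bias = Σ(y−ŷ)/n (reference minus prediction), R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²,
and relative forms divide by the reference mean ×100. Binned bias uses
half-open AGB classes [0,125), [125,250), [250,375), [375,500), [500,∞)
t/ha, matching integer bin labels 0–124 etc. Because the Bias equation's
reference-minus-prediction sign is opposite to the "overestimation shown
positive" convention customary in binned-bias tables, the binned report
carries both signs, explicitly labelled, and tests of the
regression-to-the-mean pattern use the prediction-minus-reference column.

## Synthetic scenes

The generator produces a ground-truth landscape and the full input stack a
mapping run needs, with every generative parameter known:

* **AGB field** — a kernel-smoothed Gaussian random field (correlation
  length 300 m) pushed through a lognormal transform matched to mean
  150 t/ha and sd 120 t/ha. The lognormal choice gives the heavy right tail
  real biomass distributions show, so the ≥500 t/ha validation bin is
  populated (a Gaussian at these moments would leave it empty); it reduces
  exactly to the constant mean when sd = 0. Volume is 1.7 m³ per tonne of
  AGB, within the range of published European mean Vol/AGB ratios; conifer
  proportion is a clipped Gaussian field (mean 50 %, sd 35, correlation
  600 m).
* **Bands** — each spectral band follows a saturating exponential response
  a·exp(−AGB/b) + c (decay constants b of 110–160 t/ha, reflectance ×10⁴
  scale) plus additive Gaussian noise (default sd 50). The saturation is
  the mechanism behind the overestimation of low and underestimation of
  high biomass that kNN maps from optical imagery exhibit, and the default
  decay constants place it where optical sensitivity genuinely fades.
* **Auxiliary layers** — TCD saturates in AGB; FTY is conifer where the
  conifer share exceeds 50 %, non-forest below 5 t/ha AGB; the quality band
  drops to 2000 on smooth cloud patches covering `cloud_fraction` of the
  scene; loss years are drawn on `loss_fraction` of the 30 m blocks.
* **Plots** — centres uniform over the interior (at least one footprint
  radius from the edge); responses are the footprint-weighted ground truth
  through the same circle geometry used for extraction, so extraction can
  be validated against the generator to 1e-6.

What the generator does *not* emulate: radiative-transfer physics, band
cross-correlation structure beyond the shared AGB dependence, temporal
mismatch between plot measurement and imagery, geolocation error of plots,
NFI design effects (clustering, stratification), or mixed pixels at stand
boundaries. Passing end-to-end tests therefore demonstrates the pipeline's
internal correctness and the qualitative saturation-bias mechanism, not the
accuracy attainable on real imagery.

## Study sizes used in tests

The end-to-end recovery study uses a 5 × 5 km scene (500² pixels) with
3 000 plots and k = 7, run at band-noise sd ∈ {150, 50, 0}: relative AGB
RMSE decreases strictly with noise, falls below 10 % at zero noise, and
the binned bias is positive in the lowest and negative in the highest
occupied AGB class on every tested seed at non-zero noise. Unit tests use
0.3–1 km scenes. These sizes were chosen to exercise every code path at
meaningful sample sizes while keeping the whole suite fast enough to run
habitually.

## Known limitations

* The 13-area European production layout (area delineation, plot-sourcing
  judgement for plot-free areas) is configuration, not code; the package
  supports it via `AreaConfig` but ships no continental configuration.
* Mosaicking across processing areas is out of scope; smooth transitions
  in the original system come from overlapping plot pools, which the
  configuration supports but no test re-demonstrates at scale.
* Reprojection/resampling of inputs is out of scope: all 10 m layers must
  arrive co-registered (the 30 m loss layer keeps its own grid).
* Published per-area accuracy tables depend on confidential NFI plots and
  continental imagery and are not reproducible here; what the package can
  and does reproduce is the split arithmetic, naming/encoding conventions,
  the estimator's algebra and the qualitative error structure.
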