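# Methods

## Grid conventions

All fields live on a regular latitude–longitude grid with cell-center
coordinates, latitude ascending, longitude in [−180, 180), and grid edges
on multiples of the resolution (default 0.5°). Missing/land cells are NaN
and are excluded from every statistic. Nearest-neighbour regridding
assigns each target cell the value of the source cell with the nearest
center, breaking exact ties toward the lower latitude, then the lower
longitude, so coarsening is deterministic.

One constant ties all degree↔km conversions together:
`KM_PER_DEGREE = 111.32` (spherical mean-Earth km per degree of
latitude). Cell area is (111.32·res)²·cos(lat); centroid shifts use the
same constant, so a 1° poleward shift is 111.32 km by construction.

File formats: NetCDF with CF-style `lat`/`lon` coordinates (written and
read through xarray's scipy backend), single-band GeoTIFF carrying the
ModelPixelScale/ModelTiepoint/GDAL-nodata tags (through tifffile), CSV
occurrence tables (`species,lon,lat,year,source`), and GeoJSON
FeatureCollections for regions and protected areas. Every writer produces
files the package's own readers accept.

## Synthetic scenario

The generator emulates a temperate shelf sea on a 40×40 half-degree grid
(45–65°N): SST linear in latitude from 16 °C at the southern edge to 6 °C
at the northern edge plus optional N(0, 0.3 °C) cell noise; bottom
temperature = SST − 0.5 °C (a shallow, well-mixed shelf, so surface and
bottom patterns are nearly identical); depth rising from 40 m at the
coastal strip at 0.05 m per km of distance to coast, giving a mean depth
near 90 m; salinity, primary productivity, sea ice and distance-to-coast
derived deterministically from the same seed. The future state adds a
spatially uniform warming delta, 1.27 °C by default (the upper of the two
multi-model warming estimates for such a shelf sea between a 1985- and a
2050-centred period; 0.77 °C is the companion lower estimate), to SST and
SBT only; both periods share one land mask.

What the generator does *not* emulate: interannual variability and trends
within a period, ocean circulation, spatially structured warming,
temperature–salinity covariation, and survey effort bias in sampling.
Passing tests therefore demonstrate correctness of the method chain under
known, idealized forcing — not predictive skill on real archives.

Virtual species carry a known trapezoidal niche per variable plus a depth
limit; occurrences are sampled with replacement proportional to true
suitability × detectability, jittered within the cell, with years uniform
in 1971–2000 (the training climate window). This gives every fitting
stage a ground truth.

## Occurrence preparation

QC applies four individually switchable rules in a fixed order: invalid
coordinates, records on land cells, records outside the year window
(default 1971–2000), and per-(species, cell) duplicates. Records are
aggregated to binary presence with half-open cells [edge, edge+res).
The 75/25 train/test split is done at cell level, not record level, so
spatially duplicated records cannot leak between the sets; test cells
drive ROC threshold selection only.

## Envelope model

pref_min/pref_max are the 10th/90th percentiles (linear interpolation) of
each variable at presence cells; absolute limits are the observed
min/max, optionally widened by a buffer fraction of the preferred range
(default 0). These constants are exposed as knobs because the canonical
envelope software does not publish a single fixed parameterization; this
implementation is a reconstruction of the algorithm's form, not a port.
Per-variable suitabilities combine by geometric mean by default (keeps
the output scale comparable across models with different variable
counts); the classical product rule is available. Depth acts through the
post-hoc clip rather than as an envelope variable by default, so the
relative suitability surface is not distorted by bathymetry; it may be
added as a variable via config.

## Maximum-entropy model

Features are standardized (background mean/sd) linear and quadratic terms
of each variable. The weights maximize mean presence log-likelihood of
q(i) = exp(λ·f(i))/Z (Z over background cells, default all sea cells)
minus β·‖λ‖₁, β = 0.1 by default. The optimizer is proximal gradient
ascent — a gradient step followed by soft-thresholding for the L1 term —
with backtracking line search and doubling step recovery, which makes the
penalized objective exactly non-decreasing; iteration stops when the
improvement falls below `tol` (1e-7) or at `max_iter`. Prediction applies
the *training* standardization constants, clamps standardized features to
±6 sd so extrapolated climates cannot overflow the exponential, and
rescales raw scores by their maximum (the logistic output of the
well-known desktop implementation needs a prevalence assumption and is
deliberately not reproduced).

## Dynamic simulation

Preference profiles are suitability-weighted histograms (default 20
equal-width bins per variable, max bin rescaled to 1) of each variable
under a seed distribution — here the envelope model's baseline
prediction. Carrying capacity is K_scale × the geometric mean of profile
values; variable values outside all bins contribute zero suitability
rather than an error. Each annual step applies logistic growth toward the
current K (cells with K = 0 decay at rate r, floored at zero; transient
overshoot above K is allowed), then dispersal implemented as a symmetric
exchange in which every pair of 4-neighbouring sea cells swaps d/4 of
each member's abundance, with no-flux boundaries at land and domain
edges. The exchange form (rather than "d times the neighbourhood mean")
is what makes total abundance exactly conserved when r = 0, to 1e-9
relative in the tests. The annual environmental series is a linear
per-layer interpolation between the baseline- and future-centred stacks;
years before the baseline year hold the baseline state. Defaults:
r = 0.5 yr⁻¹, d = 0.1 yr⁻¹, K_scale = 1, 1985→2050. These dynamical
defaults are declared choices — the source framework does not publish
per-species values — and the larval-advection, oxygen and pH physiology
of the full framework is out of scope (an advection hook is reserved in
the parameter object).

## Post-processing and metrics

Clipping zeroes suitability outside allowed regions (an empty region list
means no region clip) and where depth exceeds 1.5× the species' maximum
depth; the same rule is applied to both periods so the inter-period
difference is never an artefact of the clip. Thresholding zeroes values
strictly below t. The max-S+S threshold searches the unique predicted
values at held-out test-presence cells, with specificity computed against
all background sea cells not in the test presence set (presence-only data
provide no true absences, so background cells act as pseudo-absences);
ties take the smallest candidate, and a zero-discrimination map returns
its constant with a warning flag. Selection is per (species, model).

Centroids weight cell latitude by raw suitability/abundance (an
area-weighted variant exists behind a flag and is a documented
deviation). Schoener's D normalizes each map to sum 1 over the cells
finite in both maps before the L1 comparison — model outputs are relative
suitabilities, not probabilities, so the normalization is part of the
statistic. The percent overlap change adds 0.1 to the baseline D to damp
divisions by near-zero overlap. Range loss (cells left) and gain (cells
entered) are areas of set differences of the thresholded ranges, as
percentages of the baseline area.

Protected-area standardization pools suitability values over all area
cells in *both* periods per species × model before min–max rescaling;
this keeps per-cell deltas comparable across areas and bounded in
[−1, 1], where baseline-only pooling would let future values escape the
unit interval. Area membership is cell-center-in-polygon, boundary
inclusive.

## Pipeline

`rangeshift fixtures` materializes a complete synthetic dataset and
config; `rangeshift run` executes prep → fit → project → clip →
thresholds → dispersal scenarios → metrics → protected areas, writing
per-species/model/period maps (NetCDF), long-format CSV tables and a JSON
manifest (config hash, seed, per-stage counts, warnings). All randomness
flows from the single config seed through per-stage offsets, so identical
config + seed yields byte-identical tables. Alternative climate forcings
are expressed as additional future stacks in separate configs.

## Numerical notes and limitations

- Degenerate envelope (constant variable at presences) collapses to a
  step function: suitability 1 at that value, 0 elsewhere.
- Equal-width profile bins assign the closed upper edge to the last bin.
- The demo problem sizes (40×40 grid, 250–300 records per species,
  65 annual steps) were chosen so a full run completes in seconds; the
  statistics are grid-resolution limited, e.g. centroid shifts are
  accurate to about one cell width (≈55.7 km at 0.5°).
- The dynamic simulation's steady state under heterogeneous K and d > 0
  is a growth–dispersal balance near, but not exactly at, K; exact
  fixed-point behaviour holds for homogeneous K or d = 0.
- Real-data effects — sampling bias, niche truncation at domain edges,
  correlated predictors beyond SST/SBT, non-uniform warming — are outside
  what the synthetic tests can certify.
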