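# rangeshift

Multi-model projection of climate-driven range shifts for marine species
on a 0.5° latitude × longitude grid, with the downstream impact analyses
used in conservation assessments: poleward centroid shifts, suitable-area
loss and gain, range overlap between threatened and commercially exploited
species, and habitat-suitability change inside candidate marine protected
areas.

It is aimed at marine ecologists and conservation analysts who want a
self-contained, fully testable version of this analysis chain: every stage
can be driven by synthetic environmental scenarios and *virtual species*
with a known environmental niche, so model behaviour can be verified
against ground truth before any real occurrence or climate data are
involved.

## Models and statistics

Three species-distribution models are projected from a baseline to a
future climate state:

- **Trapezoidal bioclimatic envelope** (AquaMaps-style): for each
  environmental variable a trapezoid (min, pref_min, pref_max, max) is
  fitted from the 10th/90th percentiles and extremes of values at presence
  cells; suitability ramps linearly from the absolute limits to the
  preferred range and per-variable responses combine by geometric mean or
  product.
- **Maximum-entropy model**: a Gibbs distribution over grid cells,
  q(i) ∝ exp(Σⱼ λⱼ fⱼ(i)), with standardized linear + quadratic features,
  fitted to presence cells against a background by L1-penalized maximum
  likelihood.
- **Dynamic envelope simulation**: per-variable preference profiles
  derived from a seed distribution set a carrying capacity Kᵢ per cell;
  relative abundance then evolves annually by logistic growth
  A′ = A + rA(1 − A/K) and conservative nearest-neighbour dispersal, from
  the baseline year to the projection year.

Projections are clipped to allowed basins and to 1.5× the species' depth
limit, thresholded (fixed cutoffs 0.05/0.5/0.7 plus the ROC-derived
maximum sensitivity+specificity cutoff), and evaluated under no-dispersal
and full-dispersal scenarios. The impact statistics are

- latitudinal centroid  L̄ = Σᵢ Lᵢ·Abdᵢ / Σᵢ Abdᵢ, with the inter-period
  shift in km = ΔL̄ × 111.32;
- range loss/gain as percentages of baseline suitable area;
- Schoener's D = 1 − ½ Σᵢ |p_x,i − p_y,i| between per-map-normalized
  distributions, with percent change damped as
  100·(D₂₀₅₀ − D₁₉₈₅)/(D₁₉₈₅ + 0.1);
- min–max standardized habitat suitability and its 2050−1985 per-cell
  change inside protected-area polygons.

## Worked example

Generate a synthetic shelf-sea demo (two "threatened" and two
"commercial" virtual species, 1.27 °C of surface warming between the
periods, six protected-area polygons) and run the full matrix:

```bash
rangeshift fixtures --outdir demo --seed 1
rangeshift run --config demo/config.yaml
```

`demo/results/centroids.csv` then contains, per species × model ×
threshold × dispersal scenario, rows like (full dispersal, threshold 0.5):

```
      species    model  centroid_baseline  centroid_future   shift_km
virt_threat_1 envelope          58.337386        60.810067 275.258868
virt_threat_1   maxent          58.136761        60.580130 271.995897
virt_threat_1     dbem          58.431254        60.817786 265.668747
```

The 1.27 °C warming over this scenario's ~0.51 °C-per-degree latitudinal
SST gradient corresponds to an isotherm displacement of ≈2.5°, i.e.
≈277 km; all three models track it closely, the dynamic simulation
slightly less because population growth and limited dispersal lag the
moving isotherms. `overlaps.csv` holds the threatened × commercial
Schoener's D pairs and their damped percent change, e.g.

```
   threatened  commercial  D_baseline  D_future  pct_change
virt_threat_1 virt_comm_1       0.430     0.428      -0.394
virt_threat_2 virt_comm_1       0.739     0.758       2.316
```

and `range_changes.csv` and `rhs.csv` the area changes and per-protected-
area suitability deltas. A second run with the same config and seed is
byte-identical.

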