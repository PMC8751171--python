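# Methods

This note documents the models implemented by `mslur`, the synthetic
data-generating world used to exercise them, the numerical choices, and
what the test results do and do not demonstrate about real data.

## City-scale model

### Predictor construction

All spatial predictors are evaluated in circular buffers around each
long-term monitoring station, one column per (variable, radius) pair over
the radius series 50, 100, 200, 300, 400, 500, 750, 1000, 1500, 2000 m
(the synthetic study uses the 50–500 m sub-series to match its 2.4 km
extent; an extent of at least four times the largest radius keeps every
station's buffer complete). Raster buffering uses the
cell-center-in-circle rule — a cell belongs to the buffer iff its center
lies within the radius — because it is deterministic, fast at 10 m
resolution (quantization error < 1 % for r ≥ 100 m), and identical in its
point form (station extraction) and convolution form (full-grid predictor
surfaces), so a station cell and the map cell under it see exactly the
same value. Point counts are boundary-inclusive. Road densities are
clipped-length per buffer area (km/km²) per road class (trunk, primary,
secondary, tertiary, ordinary). The greening cover ratio is the buffer
mean of a continuous vegetation-cover raster (high inside the open-space
class, low elsewhere) rather than a duplicate of the open-space fraction.
Sounding indices (KINX, PWAT, CINV, LCLP, LFCV, VTOT) are consumed as a
prepared daily CSV; deriving them from raw soundings is out of scope.

Meteorology is interpolated from the weather-station network by ordinary
kriging with an exponential, zero-nugget variogram fitted by weighted
least squares to the binned empirical semivariogram (weights = pair
counts). Zero nugget makes the surface honour station values exactly,
which is the standard choice for smooth met fields; a failed variogram
fit falls back to inverse-distance weighting with a warning, and
physically bounded variables (RH, wind speed, rainfall) are clipped with
a logged count. Interpolation is daily at station targets (for the
predictor table) and on period means for map surfaces.

### AOD processing

Per-overpass AOD scenes carry a cloud mask (Clear / Possibly cloudy /
Cloudy), an adjacency mask and a near-coastline flag. Screening retains
Clear and Possibly-cloudy pixels plus coastline-flagged pixels (coastal
urban coverage would otherwise be systematically erased), Terra and Aqua
are averaged per pixel over whichever is valid, and the daily composite
is smoothed to the 10 m analysis grid by nodata-aware bilinear
interpolation.

The (station, season) response averages station PM2.5 **over the same
AOD-valid days** that form the row's AOD mean. Without this day matching
the satellite's clear-sky sampling of the autocorrelated background
biases the AOD–PM link and induces shared season-level residuals that
inflate the apparent significance of temporal covariates.

### Screening

Distance-decay radius choice maximises |Pearson r| between each family
and the residual of PM2.5 ~ AOD (ties to the smallest radius). AOD is
forced into every model and carries the regional background and gradient,
so the buffer radius is chosen by what remains for the spatial predictors
to explain; correlating against the raw response instead lets background
noise occasionally flip the radius ranking. Selection is pooled across
the four seasons (64 rows): per-season screening with 16 rows cannot
support a stepwise over ~22 candidates. The stepwise screen is
bidirectional with largest-|t| entry order (deterministic, column-order
independent); a term enters only if its p < 0.05 and all VIFs stay < 3
after entry, and any non-forced term whose p rises above 0.05 is removed.
With ~22 candidates at the 5 % entry level, roughly one chance inclusion
per run is the expected behaviour of this procedure, not a defect.

### GTWR

At each observation a weighted least-squares fit uses kernel weights on
the combined squared distance `d² = d²_space + λ·d²_time` (metres,
days); gaussian `exp(−d²/h²)` by default, bisquare optional. Hat-matrix
diagonal elements give the effective parameter count tr(S) and the
small-sample AICc `n·ln(RSS/n) + n·ln 2π + n(n+tr(S))/(n−2−tr(S))`;
`(h, λ)` minimise AICc on a grid with golden-section refinement on h.
Near-singular local systems receive a 1e-8 ridge with a warning.
Leave-one-out CV predicts each point with its self-weight zeroed.
Seasonal models are independent fits on each season's rows with the
pooled subset; map prediction solves the same local system at every
valid 10 m cell (batched), with AOD nodata propagating to the map. The
annual map is the day-count-weighted mean over seasons valid at each
cell (renormalised when a season is missing), and the annual R² pools
the seasonal fitted/observed pairs.

## Neighborhood-scale model

Raw light-scattering readings are divided by the hygroscopic growth
factor `CF = 1 + 0.25·RH²/(1−RH)` (RH as a fraction; the correction is
singular at saturation, so RH ≥ 1 is rejected). The hourly background
anomaly (background station minus its campaign mean) is subtracted,
removing hour-to-hour and day-to-day drift while preserving the campaign
mean; a ratio adjustment would be an alternative reconstruction, the
additive form is the package's choice. ΔPM2.5 is the deviation from the
site mean (each site needs ≥ 30 samples).

Samples snap to the nearest road segment within 25 m and inherit its
eight network metrics; sky view factor and point-FAI are evaluated at the
sample's own coordinates. The ΔPM2.5 regression is OLS screened with the
same stepwise rules, no forced term, and a VIF bound of 4 (the
neighborhood-scale collinearity tolerance; the city stage keeps 3).
**Predictors are centered per site before fitting.** The response is a
within-site deviation, so between-site predictor scatter carries exactly
zero response signal (the between-site design is orthogonal to the
centered response) and including it only attenuates and rotates the
coefficient vector; site centering is the fixed-effects estimator of the
within-site model. Mapping applies the fitted slopes to raw grid values
minus the stored global training means. The numeric training range of
every retained predictor is stored; map cells outside any range — or
outside road space — are masked (no extrapolation). The Δ layer is added
onto the annual city map where valid, negatives floored at 0 with a
logged count.

Because sampling sites are deliberately building-rich, open road space
sits below the training mean and the Δ layer's valid-cell mean is
slightly negative (≈ −0.8 µg/m³ on the synthetic city) while straddling
zero, as a site-centered response implies.

## Morphology indices

**Frontal area index.** `FAI = Σ_θ [A_F(θ)/A_T]·P(θ)` over the eight
principal wind directions. `A_F(θ)` is the *silhouette* area: grounded
rectangles (projected width ⊥ θ × height) are merged, not summed, so
mutually occluding buildings are counted once. Buffered FAI uses the
circle as the lot (A_T = πr² exactly, footprints clipped to the circle).

**Point-based FAI.** Each building inside the 200 m circle contributes
its wind-weighted frontal area `Σ_θ P(θ)·h·W(θ)`, apportioned over its
footprint on a square integration grid (default step R/100) by area
fraction, weighted by the decay `w(l) = ((R−l)/R)^c` (c = 2) of the
cell-center distance, normalised by the circle area. This discretization
converges as the step shrinks and reduces exactly to the buffered FAI
density when the decay is flat; a per-cell silhouette formulation was
rejected because slicing a building along the wind direction multiplies
silhouettes and the sum diverges with refinement. Frontal areas are per
building inside the integral (no cross-building occlusion), which the
flat-decay consistency check bounds at the 1 % level on the test scenes.
Steps coarser than R/10 are rejected.

**Sky view factor.** Horizon-angle scanning over the DSM for a
horizontal viewpoint: along each azimuth the maximum elevation angle
within the search distance is found by ray marching at cell-size steps,
and `SVF = (1/n)·Σ cos²φ` — the cosine-weighted (view-factor) kernel, so
a uniform 45° horizon gives exactly 0.5. The printed source formulation
with slope terms is typographically unrecoverable; the horizontal-
viewpoint form is validated against a 10⁵-ray Monte-Carlo hemisphere
caster (agreement < 0.01 on canyon fixtures). The pipeline uses a 50 m
search distance — the immediate street-canyon walls — which keeps SVF
complementary to the 200 m point-FAI rather than a near-duplicate of it;
the vectorized grid version uses 8 azimuths with ground-level observers
(rooftop cells see open sky).

**Roughness length** is the rule-of-thumb morphometric estimate
`z0 = 0.1·mean building height` over buildings whose centroid falls in
the buffer (0 when empty); wind-tunnel-calibrated schemes are out of
scope and the strategy is configurable in principle.

## Road-network metrics

Centrality (straightness, betweenness, closeness) is computed on the
primal graph with metric length weights, evaluated at segment midpoints
inserted as nodes; betweenness is normalized by (N−1)(N−2)/2 pairs per
connected component, closeness is (N−1)/Σd, straightness the mean
Euclidean/network distance ratio to other midpoints. Space-syntax
metrics use the segment dual graph (segments adjacent iff they share an
endpoint — a segment-based stand-in for an axial map, which keeps the
metric definitions while avoiding tool-bound axial-line derivation):
connectivity = degree, control = Σ 1/deg over neighbors, mean depth =
mean topological distance, integration = 1/RRA with RA = 2(MD−1)/(k−2)
normalized by the standard diamond value D_k; local integration uses the
radius-3 subgraph. Components with k ≤ 2 (or zero relative asymmetry)
yield NaN integration with a warning. All metrics are verified exactly
against dense Floyd–Warshall path-counting oracles on random graphs.

## The synthetic city and its truth

The generator (seeded; every draw flows from one `numpy` Generator
recorded in the run manifest) builds a 2.4 km × 2.4 km city at 10 m:

* **Land use**: quantile-thresholded smoothed Gaussian field (correlation
  length ≈ 150 m) with fractions residential 0.30, commercial 0.12,
  industrial 0.08, government 0.10, open space 0.40 — exact to the cell
  count by construction.
* **Buildings**: rectangular footprints (10–20 m) on built classes off
  the streets, lognormal heights (medians 45/60/15/25 m for
  residential/commercial/industrial/government, σ = 0.5) — a compact
  high-rise city whose road cells span deep canyons as well as open
  stretches; the DSM burns footprint heights over flat ground.
* **Roads**: rectilinear network with random 180–420 m spacing, split at
  intersections, all five road classes present.
* **Stations**: 16 monitors on a jittered lattice inside the full-buffer
  margin, snapped to cell centers and re-drawn off road cells
  (regulatory ambient monitors are sited away from canyon hot-spots);
  8 weather stations; bus stops every ≈ 250 m of road.
* **Population**: an independent smooth density field (500–9500
  persons/km²), deliberately *not* derived from the residential mask so
  that land-use and population effects are separately identifiable.

The generative truth is
`PM2.5(x, y, day) = background(day) + gradient + emissions + canyon`:
an AR(1) daily background (ρ = 0.6, SD 3 µg/m³) around seasonal means
(spring 20, summer 13, fall 22, winter 28 µg/m³), a linear gradient
(−2, +1) µg/m³ per km, a residential emission term (10 µg/m³ per unit
areal fraction at the true radius 300 m), and on road cells only the
morphology term `−12·(SVF−1) + 40·FAI_point` µg/m³ — street-canyon
effect sizes of a few µg/m³, the magnitude neighborhood PM2.5 models
report. Fields are floored at 1 µg/m³ with a clip count.

Observations: station readings add N(0, 1 µg/m³); AOD scenes live on a
300 m pixel grid standing in for the 1 km product at the scene's scale,
with `AOD = (regional PM − 5)/25 + N(0, 0.06)` — the satellite column
tracks the regional component (background + gradient), not street-level
increments — a spatially correlated cloud process (30 % cloud fraction,
a Possibly-cloudy rim, adjacency flags) and a south-coast flag band.
Mobile campaigns walk random road-graph paths at 0.8 m/s with 1-s
logging, 10 sites × 500 samples over three daily slots, raw readings
inflated by the RH correction factor in reverse (RH 0.30–0.92) plus
N(0, 2 µg/m³), with an hourly background anomaly shared with the
background-station series so the adjustment step is verifiable by
construction.

**What the synthetic world does not emulate**: atmospheric chemistry and
dispersion physics, wind-driven anisotropy of the canyon effect, terrain
(the scene is flat, so the elevation predictor is constant and dropped),
GPS error, instrument drift beyond the RH term, and Hong Kong's actual
geography. Passing recovery tests therefore demonstrates that the
pipeline's statistics are implemented correctly and can recover a known
generative structure at realistic noise — not that the same predictors
would be selected on any real city.

## Problem sizes and determinism

The default study is 240×240 cells, 48 days (12 per season), 64
station-season rows, 10 sites × 500 mobile samples — sizes at which the
full pipeline runs in well under a minute on one core while leaving all
recovery signals measurable. The run manifest records the configuration,
truth parameters, package versions and a SHA-256 per artifact; re-running
with the same config is bit-identical.

## Known limitations

* The gridded point-FAI used for the generative driver and map surfaces
  approximates per-cell frontal area as `height × cell width`
  (direction-averaged); the exact geometric implementation is used for
  point evaluations and validated against a fine-grid oracle.
* The GTWR temporal unit (days) and the λ grid are conventions; the
  synthetic seasons are fitted independently, so λ mostly matters when
  pooling across seasons.
* Kriging is isotropic ordinary kriging; universal/co-kriging and
  anisotropy are out of scope.
* GeoJSON/ASCII-grid I/O assumes one shared projected metric CRS;
  geographic inputs are rejected, never reprojected.
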