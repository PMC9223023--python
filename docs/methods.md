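# Methods

## The prediction model

The old-age dependency ratio is defined as `ODR = 100 × P65+ / P15–64` and
carried as a percentage throughout (17.923, not 0.17923). The predictor is
the zonal brightness total `SUM of DN = Σ DNᵢ` over a zone's *effective
pixels*: all non-nodata cells whose centers fall inside the zone polygon,
zero-DN cells included — excluding dark pixels would leave MEAN of DN
ill-defined for unlit zones and is never warranted by the data model.

Eleven curve-estimation forms link brightness x to ODR y. The
polynomial-type members (Linear, Logarithmic, Inverse, Quadratic, Cubic)
are fitted by OLS on the transformed x. The intrinsically exponential
members (Compound, Power, Sigmoid, Growth, Exponential, Logistic) are
log-linearised — OLS of ln y on the model's x-transform — and the
coefficients back-transformed. This is the behaviour of classical
curve-estimation software, and two consequences are embraced rather than
patched:

* **R² is reported on the fitting scale**, so it lies in [0, 1] and
  matches what such software prints; the original-scale R² is also
  computed for transparency (it can be negative for a badly misspecified
  back-transformed curve).
* **Growth, Compound and Exponential are one curve** under
  reparameterisation, so their fitting-scale R² agree to machine precision
  on any dataset; the comparison table shows identical rows for them by
  construction.

The Logistic form here is `y = 1/(1/μ + b0·b1^x)` with **μ the mean of x**
(the convention adopted in the source material, not the usual
carrying-capacity parameter). It is implemented as written; a
`logistic_mu_mode="fixed_bound"` switch substitutes a user-supplied bound
for users who want the conventional parameterisation. With μ on the scale
of brightness sums (~10⁵), 1/μ is negligible against 1/y, which is why the
Logistic row tracks the Compound/Growth/Exponential trio closely.

Model selection maximises the **mean fitting-scale R² across year
columns**; ties break toward fewer parameters, then fixed name order. A
model that fails on a year (e.g. a log model facing a nonpositive y)
records a missing cell, excluded from its mean, with a warning.

The selected Sigmoid `y = exp(b0 + b1/x)` with b1 < 0 is strictly
increasing in x with ceiling `exp(b0)` — aging saturates as brightness
grows. Because two observations determine the two coefficients exactly,
`recover_sigmoid_from_two_points` reconstructs a published model from any
two printed (SUM, ODR) prediction pairs; the packaged 65-city table
validates the reconstruction by back-prediction (max error < 0.001
percentage points), so the recovered b0 ≈ 3.019, b1 ≈ −4.64×10⁴ are
treated as reconstructed, not quoted, values.

The large-city filter keeps records with `round(ODR, 2) ≥ 13.71` and
`SUM of DN ≥ 115,762`. Rounding before thresholding is deliberate: it
reconciles a 2-dp printed cutoff with a city predicted at 13.706.

## Raster processing

Rasters carry integer DN in [0, 63] with a nodata mask and a rotation-free
GDAL-style geotransform; I/O uses the ESRI ASCII grid text convention
(equivalent single-band information to a GeoTIFF) with nodata defaulting
to 255. Reprojection targets a spherical Albers equal-area conic
(authalic radius; central meridian 105°E, standard parallels 25°N/47°N,
configurable) — the conventional China-extent equal-area choice; at 1 km
cells the sphere-vs-ellipsoid difference is far below one cell.

Resampling offers nearest, bilinear and cubic convolution (Keys kernel,
a = −0.5). Cubic can overshoot the DN range, so outputs are **clamped to
[0, 63] but kept fractional**: rounding would bias zonal sums, and the
integer invariant is only asserted of source rasters. Nodata propagates
conservatively — an output cell is nodata if any cell in its interpolation
support is nodata or off-grid. When source and target CRS coincide the
output grid anchors at the source origin, making identity
nearest-resampling bit-exact.

Cell-to-zone assignment uses the cell-center point-in-polygon test, with
boundary centers going to the first zone in ID-sorted order — a
deterministic rule independent of file ordering. Zones without effective
pixels are kept in the assignment (empty, logged) and omitted from zonal
statistics. Raster year and ODR year are treated as free metadata; no
temporal alignment is attempted.

## Spatial statistics

Queen contiguity: two zones are neighbors iff their polygons share at
least one boundary point (vertex or edge). Moran statistics default to
row-standardized weights; Gi\* always uses binary weights with the unit
included in its own neighborhood. Under row standardization the identity
`Σᵢ Iᵢ / n = I` holds exactly and is tested to 1e-12.

* **Global Moran's I**: computed exactly from the cross-product
  definition. Inference is either the closed-form randomization moments
  (Cliff–Ord; needs n ≥ 4 since the variance denominator carries (n−3))
  with a two-sided normal p, or permutation with two-sided pseudo-p
  `(1 + #{|I_perm − E| ≥ |I_obs − E|}) / (1 + n_perm)`. Both are reported
  by the pipeline because a published z of analytic style and a
  permutation p answer slightly different questions.
* **Local Moran's Iᵢ (LISA)**: expectation −1/(n−1) under the null. (The
  source material renders E(Iᵢ) with a positive sign; a positive constant
  contradicts the no-autocorrelation null, so the standard negative value
  is used.) The variance comes from conditional permutation — xᵢ held
  fixed, the other n−1 values shuffled into its neighborhood — and
  zᵢ = (Iᵢ − E)/sd feeds the significance classes. Quadrants HH/LL/HL/LH
  come from the signs of the centered value and its spatial lag; only
  pseudo-p ≤ 0.05 units should be colored on cluster maps.
* **Getis-Ord Gi\***: the z-valued self-inclusive concentration statistic
  with S the population standard deviation (divisor n). When a unit's
  neighborhood spans the entire dataset the denominator is exactly zero
  (the statistic has no variance); such units are reported NaN/ns with a
  warning rather than failing the run. Classes: hot/cold at |z| ≥ 1.96,
  strong at |z| ≥ 2.58, boundaries inclusive.

Islands (no neighbors) are retained in the weights, logged, excluded from
local statistics with an explicit flag, and refuse the global statistic
only when *no* unit has a link.

## Synthetic data

The generators replace three undeposited inputs and are pure functions of
(parameters, seed):

* **Lattice zones**: square tilings whose Queen adjacency is known in
  closed form (corners 3, edges 5, interior 8).
* **DN rasters**: per-zone Poisson draws at a given intensity, clipped to
  [0, 63]. Poisson (not Gaussian) respects integer DN; the clip mimics
  sensor saturation. Note clipping truncates only the upper tail, so at
  intensity 63 the zonal mean converges to E[min(Poisson(63), 63)] ≈ 59.8,
  not to 63 — tests assert the analytic clipped mean.
* **ODR tables**: `odr = exp(b0 + b1/x + ε)`, ε ~ N(0, σ²) on the log
  scale, so the log-linearised OLS estimator is correctly specified and
  parameter-recovery tests are sharp. Defaults: the reconstructed
  coefficients (b0 = 3.019, b1 = −46,440) and σ = 0.05.
* **SAR fields**: `x = (I − ρW)⁻¹ε` with row-standardized W, |ρ| < 1;
  ρ = 0 reduces to i.i.d. noise. These provide ground-truth spatial
  dependence for power studies.

The default scenario uses a 6×5 lattice (≈ the 31 provinces) with 80×80
pixels per zone and DN intensities in [5, 60], so zonal sums span
~3×10⁴–4×10⁵ — the magnitude of the real municipal brightness totals, and
the operating range of the reconstructed Sigmoid.

What the generators do **not** emulate: sensor geolocation error, gas
flares, inter-satellite drift and intercalibration, irregular
administrative geometries, and the demographic processes behind real ODR
series. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not predictive validity on real census
data.

## Problem sizes and numerical choices

Simulation-backed checks run at: 100 random fixtures (n ≤ 50) for oracle
equivalence at 1e-12; exhaustive permutation calibration at n ≤ 6; a
10×10-lattice SAR power study at 100 seeds × 999 permutations; 200
replicates of n = 31 for estimator bias; 100 replicates of ten 31-province
years for model ranking. These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping the default suite around
10 seconds.

Degenerate inputs are errors, not silent results: constant fields (zero
variance), coincident x in the two-point solve, nonpositive y under a log
transform, empty rasters, all-island maps. Design matrices are
column-scaled before rank checks and least squares so polynomial fits at
brightness magnitudes (~10⁵, x³ ~ 10¹⁶) remain well conditioned. The
pipeline fits the selected model on the most recent year label — which
year's coefficients drive the municipal prediction is otherwise an open
choice — and funnels all randomness through one seed, making reruns
byte-identical.
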