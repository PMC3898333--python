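# Methods

## The quantification problem

Isolated islets of Langerhans range from ~20 to over 400 μm in diameter.
The islet equivalent (IE) normalizes preparations to the volume of a
150 μm sphere, 1 IE = (π/6)·150³ ≈ 1.77 × 10⁶ μm³. In the conventional
workflow islets are tallied in 50-μm diameter bins and each bin count is
multiplied by a fixed factor; in the refined variant the factors are
adjusted for the within-bin size distribution. Both assume islets are
spheres of uniform tissue. Direct cell counts of dissociated rat islets
contradict that: isolated islets are oblate (mean axis ratios
b/a = 0.82, c/a = 0.60), and larger islets contain proportionally more
non-cellular space, so cell number grows much more slowly than the
diameter cube.

## The conversion model

The package's central object is a cubic polynomial mapping measured
diameter d (μm) to cells per islet,

    cells(d) = c₃d³ + c₂d² + c₁d + c₀,

with the built-in `kansas-rat-2012` coefficients
(−0.0001, 0.0912, −6.2162, 182.1125) stored at full printed precision,
valid on 20–350 μm, and anchored by 943 cells per 150-μm (1 IE) islet.
Because the leading coefficient is negative, the cubic has a shallow
local minimum near d ≈ 36 μm (≈ 72 cells) and is strictly increasing
above ~40 μm. Model policy decisions:

* **No extrapolation.** Requests outside the valid range raise. The
  cubic turns negative below ~14 μm and is unconstrained above 350 μm;
  silently extrapolating a fitted cubic is the classic failure mode.
* **The sub-40-μm dip is kept.** It is part of the published model; a
  warning is emitted for predictions below 40 μm.
* **Reference cells/IE is a model field** (default 943) so recalibrated
  models carry their own anchor.

`CellCountRegressor` refits the polynomial by (optionally weighted)
least squares, exposing scikit-learn's `fit`/`predict`/`score` protocol.
The exported model's valid range is clamped to the span of the training
diameters.

## IE estimators and factor rules

* `ie_exact(d) = (d/150)³` — per-islet sphere conversion.
* `endpoint_mean_factor(lo, hi) = (lo³ + hi³)/(2·150³)` — the
  conventional binned factor; on the six 50-μm bins from 50 to 350 μm it
  yields 0.167, 0.648, 1.685, 3.500, 6.315, 10.352. The factors are
  derived, not transcribed; `BinningScheme.from_factor_table` accepts an
  explicit published table when exact replication of a source is wanted.
* `density_expectation_factor(lo, hi, density) = E[d³]/150³` under the
  normalized within-bin density — the refined rule. With a uniform
  density the closed form (hi⁴ − lo⁴)/(4(hi − lo)·150³) applies; by
  strict convexity of d³ it always lies below the endpoint-mean factor
  (Hermite–Hadamard), which is the refined method's downward correction.
  Arbitrary densities are integrated with `scipy.integrate.quad`; a
  numeric `density` is treated as a point mass.

Bin membership is half-open [lo, hi), so a 100-μm islet falls in the
100–150 bin; this avoids double counting and matches the category
labels of the calibration table. The default minimum countable diameter
is 50 μm (where the conventional table starts); islets below it are
reported as excluded, never silently dropped. Diameters at or beyond the
last edge raise by default, since the published workflow gives no policy
for them; `overflow="extrapolate"` extends the scheme with same-width
endpoint-mean bins instead.

## Validation statistics

* **R²** = 1 − SSE/SST. Fitting per-islet data reconstructed from the
  category summaries yields R² ≈ 0.84; fitting the 12 category means
  directly yields R² ≈ 1 because the between-category scatter is nearly
  cubic — the published 0.8 is a per-islet quantity.
* **ANCOVA** compares whole regression curves (all polynomial
  coefficients free per group) by an extra-sum-of-squares F test:
  F = [(SSE_pooled − SSE_separate)/df₁] / [SSE_separate/df₂]. The
  default diameter cap is 250 μm because young animals lack larger
  islets, leaving no shared support above it.
* **Pearson r** (inter-method reliability) and **CV%**
  (100·SD/mean, n−1 denominator) use scipy with input validation.
* Group comparisons use the pooled-variance Student's t test; Welch's
  form is available behind a flag. No multiple-testing correction is
  applied — comparisons are reported as single pairwise tests.

## Synthetic data

The generator emulates the calibration study's published structure; all
randomness flows through explicit seeds.

* **Calibration draws** (`simulate_calibration_points`): for each of the
  12 categories (50–325 μm), nᵢ counts from Normal(meanᵢ, SEMᵢ·√nᵢ) at
  the category diameter, floored at 1 cell; 577 islets in total.
* **Preparations** (`simulate_prep`): diameters either replay the
  per-category allocation or follow a lognormal (median 90 μm,
  σ_log 0.45, truncated to 50–350 μm) — a generic small-islet-heavy
  profile chosen as realistic for rodent isolations, not a published
  distribution. True cell counts are drawn around the model curve (or,
  with `count_center="category_means"`, around the interpolated category
  means) with the diameter-interpolated category SD.
* **Count-noise distribution.** Per-islet counts use a gamma with the
  target mean and SD rather than a clamped normal. At the 50-μm category
  the reconstructed SD (≈177) exceeds the mean (92), so clamping a
  normal at 1 cell would inflate the small-islet mean by ~5% and
  manufacture a spurious small-vs-large difference under per-cell
  normalization; the gamma keeps counts positive while preserving the
  mean exactly. The explicit Normal draw is retained where the
  calibration-R² replication prescribes it, where only the dispersion
  matters.
* **Counting experiments**: two methods observe each size category's
  true mean count with multiplicative normal noise of a given CV%.
* **Assay groups** (`simulate_assay_groups`): 20 experiments per size
  class, ≥50 small (50–100 μm) and ≥20 large (200–300 μm) islets per
  experiment; the replicate readout is Σ true cells × per-cell content,
  with the content drawn once per experiment (DNA 6.05 ± 0.69 pg/cell,
  protein 0.58 ng/cell defaults). `size_effect` tilts the content
  linearly with diameter (fractional change per 150 μm); 0.4 suffices to
  make per-cell and per-IE comparisons disagree in sign, the proinsulin
  scenario.

What the generator does **not** emulate: measurement error in the
diameters themselves, islet purity and sampling design, animal-level
clustering (replicates are treated as independent, matching the
published analysis), and any mechanistic model of intra-islet dead
space — the cubic is taken as the mechanism-free ground truth, so
passing tests demonstrate internal consistency of the estimators and
the normalization logic, not new biology.

## Numerical choices and problem sizes

* Polynomial fits use `numpy.linalg.lstsq` on a Vandermonde design;
  weighted fits scale rows by √w. Noiseless recovery is exact to 1e-8.
* The parameter-recovery check fits with inverse-variance weights
  (1/SD(d)²), the efficient estimator when the heteroskedastic category
  noise is known; unweighted OLS lets the large-islet variance (SD up to
  ~1540 cells) dominate the small-diameter predictions.
* Monte-Carlo checks use 10⁵ uniform draws per bin (binned-vs-exact IE
  expectation), 1000 replicates for ANCOVA type-I/power rates, 200
  seeded runs for the normalization-bias rates, 100 for parameter
  recovery, and 50 for the median calibration R² — sizes at which the
  asserted margins are stable across seeds while the whole suite runs in
  well under a minute of simulation time.
* Comparison tolerances in tests follow the precision of the quantity:
  hand-derived constants to ≤ 5e-6 absolute, printed two-decimal values
  to 0.01, stochastic rates against pre-registered binomial bands
  (99.9% around the nominal rate).

## Known limitations

* The conversion model is for rat islets; no human model is provided.
* Exact reproduction of the published regression coefficients is not
  attempted: the original per-islet data and fitting software are not
  available, so closeness is asserted at the category diameters instead.
* Published small-vs-large assay tables cannot be reproduced numerically
  without the raw per-experiment data; the package reproduces their
  direction and derived worked ratios.
* The binned estimators assume the recorded diameter is the islet's
  effective spherical diameter; ellipsoid volume support is provided but
  no 2-D/3-D image-derived shape correction.
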