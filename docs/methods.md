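# Methods

This note documents the models, parameter choices and numerical conventions
behind paqikit, and what the synthetic test domain does and does not
demonstrate about real data.

## Concentration estimation

### Input screening

Candidate predictors are screened on an ordinary linear model of the observed
concentration by forward selection with backward elimination. At each cycle
the candidate whose partial-F p-value is smallest enters if it is below
`alpha_enter` (default 0.05); included variables whose removal p-value
exceeds `alpha_remove` (default 0.10) then leave, worst first. The procedure
is deterministic given the table. Constant columns are dropped with a
warning; a candidate whose entry would make the design singular is skipped.
Screening is a pre-filter for the network, not an inference procedure: with
the default 5% entry level roughly one spurious candidate in twenty will pass,
which is acceptable here because the network simply receives one weakly
informative input. Use a stricter `alpha_enter` when a sparse support is the
goal.

### Network and optimizer

The estimator is a fully connected feed-forward network: configurable layer
sizes, tanh hidden units, linear output. The default architecture is 8
inputs, one hidden layer of 16 nodes, one output — a single-hidden-layer
network of this width is already a universal approximator for the smooth
responses involved, and the architecture remains fully configurable through
`layer_sizes`.

Training minimizes the sum of squared errors with Levenberg–Marquardt damped
Gauss–Newton. The Jacobian of the network output with respect to all weights
and biases is computed analytically by reverse accumulation, vectorized over
samples (verified against finite differences in the tests). The damping
schedule is the classical Marquardt one: λ starts at 1e-3, is divided by 10
after an accepted step and multiplied by 10 after a rejected one. Iteration
stops on `max_iter` (default 200), on a gradient infinity-norm below `tol`
(default 1e-10), or when no downhill step exists even at λ = 1e10 — with a
finite loss that last case is treated as convergence to a stationary point;
divergence (non-finite loss) is reported with the final λ. Accepted steps
never increase the training SSE, so the stored loss trajectory is
non-increasing by construction.

Inputs and targets are z-scored by training-split statistics (zero-variance
columns get scale 1); predictions are de-standardized on output. Weights are
initialized from a seeded uniform(-0.5, 0.5)/sqrt(fan-in) scheme. With no
hidden layer the model is affine and the optimizer converges to the ordinary
least-squares solution of the training split; the tests assert agreement to
1e-6, which pins down the optimizer, the standardization and the
de-standardization algebra at once.

### Repeated random sampling and early stopping

`train_lm` repeats training over `n_runs` (default 50) random train/validation
splits (default 0.8/0.2) and returns the run with the highest validation
Pearson r. The per-run validation split also drives early stopping: training
halts after `patience` (default 25) accepted steps without improvement in
validation SSE and the parameters at the best validation point are returned.
This is the standard overfitting control for Levenberg–Marquardt regression
networks: with ~160 free parameters and a few hundred noisy stations, full
convergence interpolates observation noise (training r ≈ 0.998 while held-out
r stalls near 0.90 on the default domain), whereas early stopping restores
held-out r above 0.95. `patience=None` disables it and trains to full
convergence, which the linear/OLS oracle tests use.

All randomness in a call derives from the single `seed` through
`numpy.random.SeedSequence` spawning (one child per run), so identical calls
yield bit-identical models.

### Validation metrics

`validate` reports the Pearson correlation r between estimated and observed
concentrations and the absolute percentage error, aggregated as the mean of
per-record |Y_est − Y_obs| / Y_obs in percent. A zero observation makes APE
undefined and is reported as an error naming the record; zero-variance inputs
make r undefined, likewise an error.

## Individual indexes and the composite PAQI

`iaqi` maps a concentration through an ordered ladder of
(concentration, index) breakpoints by linear interpolation within the
containing segment; values beyond the last breakpoint return the ladder's cap
index. The result is real-valued by default — the weighting and grid maps
need the unrounded value — with an opt-in integer ceiling for reporting
conventions. The default PM2.5 and PM10 ladders (24-hour Chinese-standard
breakpoints up to index 500) ship as editable JSON data, not code, because
breakpoint tables are regulatory data that change independently of the
algorithm. Whether annual-mean concentrations should be mapped through 24-h
ladders is a reporting decision, so the table choice is deliberately
configuration.

The composite index uses index-proportional weights Q_i = I_i / Σ_j I_j,
which is the only weighting consistent with the requirements that each
weight lie in [0, 1], sum to one, and grow with its index. The published
rendering of the original weighting equations is partly illegible, so this
form — and the modification rule below — are documented reconstructions
rather than transcriptions; both are configurable.

The extreme-value modification counts s = #{Q_i in [0, 0.05)} and
t = #{Q_i in (0.5, 1]}. Only when both counts are positive — one component
dominating while another is negligible, the dust-storm configuration — are
the near-zero weights truncated to 0 and the remainder renormalized;
otherwise the weights pass through unchanged. This reproduces the motivating
behaviour (a composite that follows the dominant pollutant instead of being
diluted by a near-zero co-pollutant weight) and degenerates to Q when no
extreme exists. The rule is idempotent. Whether large weights counted by t
should additionally be boosted beyond renormalization cannot be resolved
from the source; only the truncation is applied, and t is reported for
diagnostics. The cutoffs 0.05 and 0.5 are exposed as `low_cut`/`high_cut`.
Any number of pollutants ≥ 2 is accepted, so additional particulate ladders
(PM1, PM0.5) slot in as data.

Algebraically, with unmodified weights PAQI = Σ I_i² / Σ I_i, which always
lies between min(I) and max(I) and is at least the arithmetic mean; the
tests check these identities numerically over random index vectors.

Per-cell application (`paqi_grid`) masks any cell masked in any input. Cells
whose individual indexes are all exactly zero get PAQI = 0 (the clean-air
limit) rather than an error, so a fully clean cell cannot poison a raster;
the scalar `raw_weights` keeps the strict all-zero error because a scalar
call with no pollution information is almost certainly a bug.

Classification uses half-open intervals [lo, next_lo): a value exactly on a
bound takes the upper (more severe) category, so "moderately polluted"
begins at 150 and "heavily polluted" at 200 under the default scheme, which
also ships as JSON.

## Exposure statistics

PW-PM2.5 of a zone is Σ PM_i·P_i / Σ P_i over the zone's valid cells — a
weighted mean, invariant to uniform population rescaling and always inside
the zone's concentration range. Zones with zero total population report NaN
with a warning: the ratio is genuinely undefined and reporting 0 would
fabricate an exposure level.

PC-PM2.5 is computed as Σ PM_i·P_i / n with n the zone's valid-cell count —
a population–concentration product normalized by zone area (units
µg/m³·persons per cell), which scales linearly with population and therefore
peaks in small, dense zones. The source's algebra for this quantity is not
fully legible; this product form is the reading consistent with its reported
contrast to PW-PM2.5 (it is the only simple form that ranks small dense
regions above large polluted ones), and the alternative simple-mean reading
Σ PM_i / n is available behind `form="mean"` so the choice is always
explicit, never silent.

Population rasters are treated as persons per cell; `density_to_counts`
converts persons/km² inputs using spherical-earth cell areas with the cosine
of each row's center latitude.

## Synthetic domain

The generator emulates the input stack as co-registered rasters on a
north-up 0.1° grid (default 40×40, upper-left corner 100°E 45°N):

* **Predictors** — Gaussian random fields (white noise smoothed with a
  Gaussian kernel of width `smoothness`, default 4 cells), affinely mapped to
  realistic levels and clipped to physical ranges: WS ≥ 0 m/s (mean 3, sd 2),
  RH in [0, 100]% (55 ± 18), SKT 288 ± 8 K, HPBL > 0 m (800 ± 350),
  AOT ≥ 0 (0.5 ± 0.3, a hazy-region loading), SSA in (0, 1] (0.90 ± 0.04).
* **Truth surface** — PM2.5 is a fixed smooth function of the predictors:
  a saturating AOT response (amplitude 130 µg/m³, half-saturation 0.6),
  +0.30 µg/m³ per % RH, dilution term 45·exp(−HPBL/1200 m), ventilation term
  18·exp(−WS/4 m s⁻¹), +0.08 µg/m³ per K of skin temperature above 285 K, an
  absorbing-aerosol term 12·(1 − SSA), and a weak meridional gradient. PM10
  adds a non-negative coarse component (floor 20 µg/m³ plus a
  humidity-suppressed dust term), so PM10 ≥ PM2.5 everywhere. Coefficients
  live in `truth_spec` and give domain means near 110 µg/m³ with spatial sd
  near 20 µg/m³ — a polluted-region regime in which the index ladders are
  actually exercised.
* **Stations** — `n_stations` (default 300) distinct cells sampled uniformly;
  observations are truth plus N(0, noise_sd²) noise, default sd 5 µg/m³
  (roughly 5% of the mean, a moderate instrument-plus-representativeness
  error), floored at zero.
* **Population** — a log-normal background times `n_zones` Gaussian urban
  clusters (σ = 1.5 cells) with log-normal amplitudes ~200× the background
  maximum.
* **Zones** — a Voronoi partition around randomly drawn centers, covering
  every cell.

One seed drives all sub-generators through a fixed SeedSequence spawning
order (fields, population, zones, stations), so a config reproduces its full
fixture set bit-identically.

What the synthetic domain does *not* emulate: cloud-induced retrieval gaps
beyond ordinary masking, aerosol-type misclassification, seasonal cycles,
measurement drift, spatially correlated observation error, and real
geography. Passing the recovery tests therefore demonstrates that the
estimation and assessment machinery is correct and converges — not that any
particular accuracy will be reached on real satellite retrievals, where
representativeness error and retrieval bias dominate.

## Grids and I/O

Row 0 is the northernmost row; transforms are origin-at-upper-left with
positive x step and negative y step; indices are 0-based. No resampling is
performed anywhere — inputs must share one grid and `align_check` enforces
shape and transform agreement (relative tolerance 1e-9) before every
multi-field computation. In any multi-field computation a cell masked in any
input is masked in the output. GeoTIFF I/O goes through tifffile with the
standard georeference tags (pixel scale, tie point, nodata); NetCDF through
xarray (NetCDF3). Masked cells are encoded as NaN/nodata and round-trip
exactly.

## Pipeline reproducibility

`paqikit run-all` executes simulate → train (per pollutant) → predict →
index → composite → exposure, writing every intermediate as a plain file in
a standard format so any stage can be replaced by external data. The
manifest records the configuration, seed, package version and SHA-256 of
every artifact — and no timestamps — so two runs with the same seed produce
byte-identical manifests and artifacts, which the tests assert.

## Problem sizes used in the tests

The default verification domain is 40×40 cells with 300 stations, 50
training runs and 16 hidden nodes; unit tests use smaller domains (16×16 to
24×24, 4–8 runs) chosen so the full suite and the acceptance script each
complete in seconds while still exercising every code path at the default
configuration at least once.

## Known limitations

* Training is desk-scale: the Jacobian is dense, so parameter counts beyond
  a few thousand or sample sizes beyond ~10⁴ will be slow; there is no
  mini-batching, GPU path, or alternative optimizer.
* No uncertainty quantification on predictions or exposure statistics.
* Only particulate pollutants: the full multi-pollutant AQI (SO₂, NO₂, CO,
  O₃) and health-impact functions are out of scope.
* No reprojection or resampling; inputs must be pre-aligned.
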