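# Methods

`felidniche` implements a spatio-temporal niche-partitioning analysis for
multi-area camera-trap surveys: which habitat variables — and at which
spatial scales — predict where a predator occurs, how its activity is
distributed over the 24-h cycle, how strongly that activity overlaps other
species', and which candidate prey co-occur with it. This note records the
models, the numerical choices, and what the synthetic data do and do not
demonstrate.

## Detection processing

Raw records (station, species, timestamp) are thinned to *independent
detections* with a greedy minimum-gap rule: within each (station, species)
group, scanned in time order, a record is kept iff at least `min_gap`
(default 1 h) has elapsed since the previously kept record. Ties at exactly
the gap are kept. The rule is idempotent and per-group, so stations and
species never interact. A greedy gap scan was chosen over calendar-hour
binning because the operational definition is "records obtained at least one
hour apart"; binning by clock hour would keep pairs 1 minute apart across a
bin boundary.

Detection frequency is `100 * count / trap-nights`, reported to 3 decimals.
Species with fewer than 20 independent detections in total are excluded from
co-occurrence and overlap candidate sets. Body-mass ratio tables use
heavier/lighter means rounded to one decimal; the "very similar size" flag
(ratio < 2) is applied to the rounded value, matching how such tables are
printed.

## Multi-scale habitat modelling

Covariates are rasters on a shared metric grid. For each of seven focal
radii — 120, 240, 480, 960, 1920, 3840, 7680 m — every covariate is replaced
by its circular focal mean: the mean over all cells whose centre lies within
the radius of the focal cell's centre. For a 0/1 indicator layer this is the
within-window class proportion. Numerical choices:

* window membership is decided on cell centres with Euclidean distance
  `<= radius` in metres, so membership depends only on the radius/cell-size
  ratio and is bit-reproducible;
* windows are truncated at the raster boundary (mean over available cells);
  no padding is invented;
* nodata cells are excluded from the mean and a fully-nodata window stays
  nodata;
* multi-class categorical layers must be exploded into per-class indicators
  before scaling;
* station-to-cell assignment uses half-open cell intervals `[x0, x0+cell)`.

Station values are z-scored across the analysis station set (not across
raster cells), so fitted coefficients are standardized per-SD effects; the
same station constants standardize the rasters at prediction time, meaning
surfaces extrapolate on the training scale. Survey effort (trap-nights) is
*not* standardized — its small per-trap-night coefficients are interpretable
in raw units — and is forced into every model.

Model building runs in three stages:

1. **Univariate scale scan.** For each covariate, logistic fits of
   detected/not-detected on intercept + effort + covariate(scale) at each of
   the seven radii; the radius with the lowest AIC wins, ties to the smallest
   radius. Non-converged scales are excluded from the minimum.
2. **Screening and pruning.** Variables whose best-scale univariate slope has
   p > 0.2 are dropped. Remaining best-scale columns with pairwise
   |Pearson r| > 0.7 are resolved by keeping the lower-AIC member; pairs are
   processed in descending |r| and a dropped variable cannot trigger further
   drops.
3. **All-subsets ensemble.** All 2^p subsets of the surviving terms (each
   containing the forced intercept and effort) are fitted; Akaike weights
   `w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)` use AICc by default (AIC
   selectable). Averaging is *full* (zero-substitution): absent terms
   contribute beta = 0 and SE = 0, the unconditional variance is
   `sum_i w_i [SE_i^2 + (beta_i - beta_bar)^2]`, importance is the summed
   weight of models containing the term, and z/p come from
   |beta_bar|/SE with a two-sided normal reference. Conditional averaging is
   not offered; full averaging matches the "adjusted SE" semantics of the
   reports this layout mirrors. The free-term cap is 15 (32,768 fits);
   larger candidate sets must be pre-screened.

The logistic fitter is iteratively reweighted least squares with Wald SEs
from the inverse observed information; convergence at max |score| < 1e-8 or
relative log-likelihood change < 1e-10, capped at 100 iterations. Perfect
separation is flagged (diverging coefficients beyond |beta| > 50 on the
standardized scale, or a log-likelihood within 1e-4 of zero, i.e. a
perfectly classified binary response); flagged fits are dropped from
ensembles before weight normalization.

Occurrence surfaces apply `p = exp(z)/(1+exp(z))` per cell with effort fixed
at the mean station effort (configurable scalar). Surfaces are compared by
Pearson correlation and mean absolute difference over jointly finite cells;
correlation with a constant surface is reported as undefined (NaN).

Co-occurrence ensembles use the same machinery with raw (unstandardized)
candidate-prey detection counts as predictors — per-detection effects are
then directly interpretable — and pre-screen candidate sets larger than the
cap down to 15 by univariate AICc rank. The pre-screen is an explicit
documented step (the reported ensembles record how many candidates were
available) because no principled subset rule exists for ~58 candidates under
an all-subsets cap.

## Temporal activity

Clock times map to angles by `theta = 2*pi*seconds/86400`; local clock time
is used directly (the diel periods are defined by fixed clock hours, so no
solar-time correction applies). The activity density is a von Mises kernel
density: each of the n observations contributes a von Mises bump, with
kernel concentration from the circular plug-in rule

    kappa* = [ 3 n kappa_hat^2 I_2(2 kappa_hat)
               / (4 sqrt(pi) I_0(kappa_hat)^2) ]^(2/5)

where `kappa_hat` inverts the mean resultant length with the standard
piecewise approximation. A smoothing adjustment *divides* the concentration,
so `adjust = 1` (the default) is the plug-in bandwidth unchanged and larger
values smooth more. A build-time cross-check requires the mean plug-in
concentration to lie within 20% of the concentration minimizing
Monte-Carlo-averaged integrated squared error on von Mises test cases,
guarding the formula against drift. All-identical samples are capped at
concentration 5000 and flagged. Densities are evaluated on a 128-point grid
(denser grids change Delta_1 by < 0.005) and renormalized so the wrapped
trapezoidal integral is exactly 1.

Diel periods are dawn 05–07, day 07–17, dusk 17–19, night 19–05 (wrapping).
Period masses integrate the density on a fine per-period subgrid and are
normalized so the four masses sum to exactly 100%; per-hour rates divide by
period length.

The coefficient of overlapping Delta = integral of min(f, g) is estimated by
Delta_1 (grid integration of the two KDEs) when the smaller sample has fewer
than 75 records and by Delta_4 (KDEs evaluated at the opposite sample's
points, each sample keeping its own bandwidth) otherwise. Density ratios in
Delta_4 are floored at 1e-12; estimates are clipped to [0, 1]. Delta is
symmetric, rotation-invariant, and Delta_1(f, f) = 1 exactly on a shared
grid.

## Smoothed-bootstrap inference

Each bootstrap replicate redraws both samples from their fitted KDEs (an
observed point chosen uniformly with replacement plus von Mises kernel noise
at that sample's kernel concentration), re-estimates both bandwidths, and
recomputes Delta with the point estimate's estimator; 10,000 replicates by
default, reproducible under an explicit seed.

The smoothed bootstrap convolves the data with the kernel *twice*: replicate
samples are over-dispersed relative to the data, so replicate Delta values
are biased upward relative to the point estimate, and a raw percentile
interval of the replicates inherits that shift (measured coverage of the
true overlap falls to ~70% at nominal 95%). The default interval is
therefore the mean-centred percentile interval: percentiles of the replicate
values recentred so their mean equals the point estimate. This is the
standard bias-corrected percentile variant recommended for these overlap
estimators, and restores ~94% empirical coverage in the package's own
simulations. The raw interval remains available (`ci_type="perc"`).

A felid's overlap profile across its candidate set is classified against the
set's empirical percentiles (linear interpolation): Delta < P5 is
significantly low, P5 <= Delta < P10 relatively low, Delta > P95
significantly high, P90 < Delta <= P95 relatively high, anything else
unclassified. Strict inequalities at the outer thresholds mean
boundary-equal values fall into the milder category. Sets with fewer than 10
candidates warn that the thresholds are unstable.

## Synthetic data

The generator reproduces the statistical structure the pipeline assumes:

* **Landscapes** — Gaussian-smoothed white noise with kernel length equal to
  the stated autocorrelation range (the simplest field with a controllable
  range, sufficient for scale-recovery tests); continuous layers
  standardized over cells, categorical layers thresholded at a quantile so
  the indicator covers the stated fraction of cells. Default extent 128
  cells of 120 m (15.4 km): broad enough that independently generated fields
  stay effectively uncorrelated across the clustered station sample.
* **Stations** — 578 stations in 10 clusters (clusters stand in for study
  areas, matching the scale of a large multi-area survey), normal scatter
  with 900 m SD around cluster centres, truncated-normal trap-night effort
  with mean 125 and SD 40 (no per-station effort distribution is published
  for such surveys; 125 trap-nights is a realistic multi-month deployment
  and the value is configurable).
* **Detections** — occurrence is logistic in true-scale focal covariates
  (standardized across stations) plus effort; counts are
  presence × (1 + Poisson) so occupancy, not abundance, carries the signal.
* **Activity** — von Mises mixtures for the four diel archetypes
  (nocturnal, diurnal, crepuscular, cathemeral).
* **Communities** — independent Poisson prey counts per station; felid
  presence logistic in prey counts with specified per-detection
  co-occurrence effects; felid-on-felid dependencies are rejected.

Every generator is a pure function of (config, seed). What the synthetic
data do *not* emulate: imperfect detection (no occupancy-style observation
model), animal movement and home-range structure, realistic geography,
spatial autocorrelation of detections beyond what the covariates induce, and
seasonal or lunar activity modulation. Passing recovery tests therefore
demonstrate that the estimation chain inverts its own generative assumptions
at survey-scale sample sizes — not that those assumptions hold for any real
survey.

## Problem sizes used in validation

Monte-Carlo suites run at the sizes their claims are stated for: scale
recovery with 100 replicates of 400 stations on a 128-cell landscape
(7 radii); end-to-end importance recovery and null-pipeline false-positive
rates with 100 replicates of 500 and 300 stations on three radii
(240/960/3840 m — one per scale tier); prey-effect sign recovery with 100
replicates of 500 stations; bootstrap coverage with 200 simulated pairs of
n = 200 at B = 500. The three-radius grid and B = 500 are the package's
scaled-down validation conditions; analysis defaults remain the seven radii
and B = 10,000.

## Known limitations

* No occupancy modelling: detection probability is assumed unrelated to the
  covariates of interest; the occurrence models describe where detections
  happen, not corrected presence probability.
* No spatial random effects: clustered stations are treated as independent,
  which anti-conservatively narrows habitat-model SEs (mixed models are out
  of scope).
* All-subsets enumeration is capped at 15 free terms; larger candidate sets
  are pre-screened by univariate AICc, which can drop a variable that only
  matters jointly.
* The overlap coefficient compares marginal diel densities; it says nothing
  about joint spatio-temporal encounter rates.
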