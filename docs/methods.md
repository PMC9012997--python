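# Methods

This note records the statistical procedures the package implements, the
choices made where conventions diverge, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Event definition

A compound o-t-event day requires a *strict* exceedance of both
thresholds ("surpassing"): MDA8O3 > 100 µg/m³ and TX > ^80TX. Days with a
missing input have missing events; the compound indicator is the pointwise
AND of the two component indicators.

**MDA8 derivation.** 8-hour running-mean windows are labelled by their
ending hour h ∈ {1..24} of a day and cover hours h−7…h, drawing on the
previous calendar day for h < 8 (the EU convention; an interior-only mode
is available). A window is valid when at least 6 of its 8 hours are valid,
its mean running over valid hours only; a day's MDA8O3 is the maximum over
its valid windows and requires at least 18 of them. These two conventions
are configurable because monitoring networks differ; the defaults follow
EU air-quality practice.

**Temperature thresholds.** For each calendar day of the season the TX
values within ±15 days across all base years are pooled and the empirical
80th percentile taken with linear interpolation between order statistics.
Near the season edges the window reaches into out-of-season days when data
exist; the calendar is never wrapped. A pool of at least 100 values is
required per day. With the default 15-year base period a pool holds ~465
values, so the percentile estimator carries a sampling sd of ≈ 0.066
standard deviations of the underlying TX distribution — threshold noise
that any percentile-based event definition at this sample size inherits.
By construction the t-event rate converges to 20 %.

## Station pairing

Each ozone station is assigned the nearest temperature station within
15 km and 200 m altitude difference (ties: smaller altitude difference,
then lexicographic id). Pairs must exceed 75 % joint seasonal coverage
(both variables present), read as a strict inequality. When two ozone
stations claim the same temperature station, the higher-coverage pair
wins, so no temperature series serves two locations. Pair metadata
(coordinates, altitude, type) comes from the ozone site. Distances are
great-circle with Earth radius 6371.0 km.

## Regionalization

Clustering features are the concatenated per-station standardized TX and
MDA8O3 daily series over the base-period season (each block standardized
to mean 0, sd 1 per station). Missing values are first filled with the
cross-station mean of the same date ("network" mode, the default),
which preserves the day-to-day synoptic signal the clustering targets; a
per-station calendar-day mean mode exists as an alternative reading.
Imputation precedes standardization.

Ward variance-minimization linkage on Euclidean distances produces the
dendrogram (via scipy). The cluster count is the k ∈ [k_min, k_max]
(k_min = 4) with the largest drop between successive merge heights; if
that gap does not exceed 1.5× the median candidate gap the data are
treated as featureless and k_min returned. This operationalizes an elbow
read manually from a dendrogram, which cannot be automated faithfully —
the dominance ratio is the tunable that controls how pronounced an elbow
must be.

New stations are assigned by minimal Ward distance increase,
n_c/(n_c+1)·‖x − c‖² for a cluster of size n_c with centroid c (ties to
the smaller label). Representative stations are, per region and
background type present, the station closest to the region centroid in
feature space, ranked across types by that distance.

## Weather typing

Daily MSLP fields are standardized per grid cell over time (row-major
flattening, parameters stored for reuse on new data). Raw-anomaly and
area-weighted preprocessing variants were considered and rejected for the
default because per-cell standardization makes the SOM's Euclidean
geometry comparable across the domain without latitude weighting.

The SOM is rectangular with a Gaussian neighborhood; sigma and learning
rate decay asymptotically (halved at the training midpoint), weights are
initialized from randomly drawn training vectors, and training is fully
deterministic given the seed. Grid sizes between 4 and 20 nodes are
candidates; the Bauer–Pawelzik topographic product — the log-average over
nodes and neighborhood orders of the weight-space/map-space distance-ratio
products — is the selection criterion, minimized in absolute value (0 is
ideal; the sign indicates whether the map dimension is too low or high).
In practice |TP| is small for every well-trained rectangular map on
smooth pressure data (observed magnitudes 0.005–0.04, bracketing values
reported for this method in applications); it diagnoses topology
preservation and should not be expected to recover a planted pattern
count. Weather-type codes are 1-based row-major node indices; days are
coded by the nearest node, ties to the lowest index; empty-node counts
are reported because scenario data tend to concentrate on fewer nodes.

## Predictors and ESM preparation

Station predictor series are the mean of the 3×3 grid-cell block centred
on the station's cell (clipped at domain edges, the mean over available
cells — clipping was preferred over padding to avoid inventing data).
Predictors are standardized over the base period with stored parameters.
Within-region agreement is screened by pairwise Spearman rank correlation
with a 0.5 flag level.

ESM fields are bilinearly regridded to the reference grid, then
bias-corrected by monthly linear scaling: the additive offset of month m
is the reference monthly mean minus the historical-ESM monthly mean,
applied to historical and scenario segments alike. The correction is
additive for all variables including SSRD (a multiplicative option exists
behind a flag but is off; "mean difference" correction is the stated
method). Offsets are computed on all twelve months. MSLP is corrected per
grid cell *before* weather types are assigned. Corrected-historical
monthly means match the reference exactly (machine precision) whenever
the two climatologies share a period — the module's oracle property. The
two-sample Kolmogorov–Smirnov test (asymptotic p) reports distributional
similarity of reference and corrected ESM predictors; it never gates the
pipeline. For projections, historical and one scenario series are merged
and then standardized jointly, so a scenario's mean shift survives
standardization.

## Downscaling models

Outcomes are binary event indicators; predictors are the four
standardized meteorological series plus the weather-type code, entered as
a single standardized numeric column (a one-hot option exists but is off,
matching the single-coefficient treatment of the synoptic predictor).
Because events are the minority class, training data are rebalanced to
exact 50/50 with SMOTE: each synthetic sample is a uniform convex
combination of a random minority sample and one of its 5 nearest minority
neighbours; originals are preserved.

Logistic regression is fit by unpenalized maximum likelihood (statsmodels
Logit, Newton); Wald p-values come from the observed information matrix.
Perfect separation is flagged and the capped-iteration fit returned with
a warning so that coefficients stay interpretable. Backward elimination
drops the single worst predictor with p > 0.05 per iteration and refits
until all retained predictors are significant; if everything is
eliminated an intercept-only model is returned with a degenerate flag.
Drivers are ranked by |standardized coefficient| (ties resolved in the
fixed column order GH, MT, SH, SSRD, WT); the top three are MID, SMID,
TMID, signs preserved.

The probability threshold p\* is calibrated in an upstream stratified
10-fold CV: per fold, SMOTE → elimination → fit on the training part, and
|precision − recall| on the validation part for every threshold in
{0.01, …, 0.99}; p\* minimizes the fold-mean (ties: nearest 0.5, then
smaller). Model evaluation nests all of this in an outer stratified
10-fold CV so validation folds never contain synthetic samples; the
report carries fold-mean P, R, F1, an out-of-sample McFadden pseudo-R²
(1 − lnL/lnL_null on held-out probabilities) and the events-per-variable
ratio. SMOTE nested inside CV is the leakage-safe reading of rebalancing
plus cross-validation; fold construction is stratified with a fixed seed.

## Projections

Fitted station models are driven with bias-corrected,
merged-standardized ESM predictors (weather types via the trained SOM,
using the training standardization); a day is an event when the modeled
probability reaches p\*. Only season days are scored, with the same
April–September season as training. Event days are counted in 20-year
slices — historical 1995–2014, midcentury 2041–2060, late century
2081–2100 — and changes reported as (n_future − n_hist)/n_hist × 100,
computed per ESM and then ensemble-averaged (mean of changes, not change
of pooled counts), alongside median/min/max and the count of models
sharing the majority sign. A configurable quality gate (default F1 ≥ 0.5)
can exclude weak-linkage stations from projection. Raw (unstandardized)
MT slice anomalies provide a stationarity diagnostic: anomalies above
2.7 °C warn that the trained relation is being extrapolated; above 4 °C
the stationarity assumption is doubtful.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
assumes, with every planted label recorded:

- **TX**: region mean + seasonal cosine (peak mid-July) + a region-shared
  AR(1) synoptic term (coefficient 0.7, the regionalization signal) +
  station noise. **MDA8O3**: region intercept + slope·TX + noise, slope
  3 µg/m³ per °C by default (the direct, approximately linear ozone
  response to temperature that motivates the compound-event framework).
  Missingness is completely at random, 5 % per variable by default,
  matching a high-coverage station regime.
- **Grids** (1° step): MSLP draws one of n planted smooth basis patterns
  per day plus noise; MT spatially interpolates the region synoptic terms
  through Gaussian footprints, so 9-cell means track station TX; GH, SH
  and SSRD load moderately on the synoptic state and carry independent
  variable-specific weather, so predictors correlate without being
  collinear. The default domain is a compact 45–60° N, 0–20° E box
  covering the synthetic station region — the generator's invariant is
  that the grid covers all stations, and a continent-scale domain would
  multiply memory without adding test power.
- **Pseudo-ESMs**: the same generative process re-drawn with a
  model-specific seed (distinct models have distinct internal weather),
  plus known additive monthly biases per variable and, for scenario runs,
  a linear MT warming trend in °C per decade anchored at 2015 (historical
  1995–2014 is trend-free). Default trends of 0.30 and 0.55 °C/decade
  yield late-century (2081–2100 vs 1995–2014) anomalies of ≈ 2.3 and
  ≈ 4.2 °C, a moderate and a strong forcing pathway.
- Real calendar dates with leap days throughout; the season filter is
  applied downstream.

What the generator does **not** emulate: ozone chemistry and its
nonlinearities (no plateau at extreme heat, no precursor or transport
effects), spatially heterogeneous missingness, instrument drift or
inhomogeneities, non-Gaussian weather regimes, and internal-variability
structure beyond AR(1). Tests passing on these data therefore demonstrate
that the estimators recover the structure they assume — not that real
ozone–temperature relationships satisfy those assumptions.

## Numerical and design notes

- Reproducibility is bitwise for a fixed config and seed; all generator
  randomness flows through seeded child generators keyed by purpose.
- Ward tie-breaks follow scipy's deterministic nearest-neighbor-chain
  order; on continuous data ties have measure zero.
- The brute-force Ward oracle, the explicit MDA8 window enumeration and
  the loop-level topographic product used in tests are independent
  implementations kept inside the test suite.
- Experiment sizes in tests and the acceptance script (60-station
  networks, 2×2 maps on ~2 200 days, 20–50 replicate fits at n = 2 700,
  3-model pseudo-ensembles) were chosen as the smallest sizes at which
  the planted structure is comfortably identifiable; they are stated in
  each test.
- Zero-variance inputs (constant series, constant grid cells), empty
  pools, folds without events, all-missing dates and dimension mismatches
  raise informative errors rather than propagating NaNs.

## Limitations

The framework assumes stationarity of the predictor–event relation under
forcing, linear-in-logit predictor effects, and a single-day event
definition (no multi-day spell structure). The elbow and topographic
product are heuristics: the first needs a pronounced variance gap, the
second measures topology preservation only. SMOTE assumes minority-class
convexity in predictor space. Percent changes are undefined at stations
with zero historical modeled events; such stations are reported with an
undefined-change flag rather than a number.
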