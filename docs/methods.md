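# Methods

This note documents the models and numerical choices behind `spoilsense`:
what each stage assumes, which parameters matter, what the synthetic study
emulates (and what it does not), and where the design was genuinely open.

## Problem setting

The response is total viable counts (TVC) in log10 CFU/g, measured by
plate counting on stored seaweed samples. Predictors come from three
instrument families with very different characters: FT-IR spectra are
high-dimensional (thousands of collinear wavenumbers) but chemically
specific; MSI feature tables are low-dimensional summaries of surface
reflectance dominated by colour; e-nose panels are 12 gas-sensor responses
to the volatile headspace. All three pipelines end in single-response PLS
regression; they differ in preprocessing and feature selection.

## Preprocessing

**Truncation.** FT-IR spectra are cut to the half-open window
[900, 2700) cm⁻¹ before any modelling, discarding the broad water band and
the noisy extremes of the acquisition range. On a 1 cm⁻¹ grid this leaves
exactly 1800 variables. The half-open convention and the 1 cm⁻¹ spacing
were chosen together so that the analysis window has this canonical
variable count; truncation selects by wavenumber value, never by column
position, so ascending and acquisition (descending) storage orders behave
identically.

**Robust normal variate (RNV).** Each spectrum is centred by its median
and scaled by its median absolute deviation (MAD). Per-spectrum statistics
are the default because they are what cancels per-sample multiplicative
scatter: for any gain a > 0 and offset c, RNV(a·x + c) = RNV(x), and the
transform is idempotent. Ensemble-wide (`global`) and per-wavenumber modes
are available for users who want robust autoscaling instead, but neither
removes row scatter. A normalization unit whose MAD falls at or below
`epsilon` (default 1e-12) is degenerate — a constant spectrum — and raises
an error naming the offending sample rather than silently dividing by
noise.

**Sensor summaries.** MSI regions of interest are collapsed to per-band
mean and sample standard deviation (ddof = 1; 36 features in the order
mean_405 … mean_970, sd_405 … sd_970). E-nose responses are the relative
resistance change (R − R₀)/R₀ against the sensor baseline.

## Feature selection

**Boosted-ensemble importances (FT-IR).** Least-squares gradient boosting
(squared-error loss, 100 learning cycles, learning rate 0.1, tree depth 3,
no subsampling — all configurable) ranks wavenumbers by the total
squared-error reduction attributable to their splits, summed over all
trees and normalized to 1. The retention rule is deliberately
data-adaptive: keep features with importance at or above the mean
importance (`threshold_mean`), with `top_k` as an alternative. On the
synthetic study this keeps ~40–50 of 1800 wavenumbers; no target count is
hard-coded because the appropriate reduction depends on how concentrated
the signal is.

**Bimodality screen (MSI / e-nose).** For each feature, one- and
two-component Gaussian mixtures are fitted to its values across samples
and compared by BIC = −2·loglik + n_params·ln(n), with 2 parameters for
one component and 5 for two. The feature survives only if two components
win. The rationale: across a storage trial spanning fresh and spoiled
samples, any feature that actually tracks microbial state has at least two
modes; a unimodal feature varies for reasons unrelated to spoilage.
Zero-variance features are dropped with a warning rather than an error,
and an all-unimodal table is a hard error ("no informative features").

**EM details.** The two-component fit uses EM with a median-split
initialization plus four seeded random quantile restarts, a log-likelihood
tolerance of 1e-6, at most 500 iterations, and a variance floor of
1e-9·var(x) to keep components from collapsing onto single points. The
per-iteration log-likelihood trace of the winning restart is retained on
the result object, so the EM monotonicity guarantee is directly testable.
The implementation is cross-checked in the test suite against an
independent mixture-model implementation on the same data.

## PLS and the knee-point

PLS (NIPALS, single response) is fitted on mean-centred, unit-variance
columns — standard chemometrics practice; RNV has already handled row
scatter. Fitted models are stored as original-space coefficients plus
intercept, so prediction is a plain affine map and serialized models need
no refit. With the component count equal to the rank of centred X,
single-response PLS reproduces ordinary least squares; this property is
used as an oracle test.

The component count is selected from the cumulative
explained-response-variance curve (entry k = training R² of a k-component
fit, computed from nested regressions on the orthogonal score vectors,
which makes the curve non-decreasing by construction). The knee-point of
this curve is found by two-line fitting: for every interior breakpoint,
straight lines are least-squares fitted to the head and tail (sharing the
breakpoint), the breakpoint with minimal total SSE wins (smallest index on
ties), and the rounded abscissa of the two lines' intersection — clamped
to the valid range — is the selected count. Two degenerate cases are
defined explicitly: a curve already linear to relative SSE 1e-10 has no
knee and yields the maximum count, and parallel head/tail lines yield the
breakpoint itself. CV-RMSE-vs-components is available as an alternate
selection curve.

Calibration runs k-fold cross-validation (default 10 folds) repeated over
Monte-Carlo repartitions (default 10), recording a repartitions × folds ×
components RMSE grid. The final model is refitted on the entire training
partition with the selected count; cross-validation is for selection and
reporting only. Feature selection happens once on the full training
partition, before the CV loop — matching the sequential design of the
workflow this package implements; users worried about selection bias
should validate on genuinely external splits (the year-holdout scheme
exists for exactly this purpose).

## Splitting and metrics

Random splits draw test samples uniformly without replacement from a
seeded generator; fractional sizes round half up, and explicit counts are
first-class because published cohort counts are not always reproducible
from a fraction. Year-holdout splits place every sample of the held
harvest years in the test set, optionally plus a random draw of
earlier-year samples, and guarantee no held-year sample ever trains.

Reported metrics are the OLS fit of predicted on actual TVC (slope α,
offset β, R²) plus the RMSE of predictions against the identity line.
RMSE is deliberately independent of the fitted line: predicted = actual + 1
gives α = 1, R² = 1, RMSE = 1, separating calibration bias from scatter.
Cross-validation rows pool out-of-fold predictions over all repartitions
(each sample appears once per repartition), which is deterministic given
the seed; per-repartition averaging is the obvious alternative and gives
very similar numbers at these sizes. Predictions are reported unclipped
and may fall below 0 log CFU/g on pathological inputs.

## The synthetic study

The generator exists so the pipeline is verifiable end to end; its
defaults are fixed to the structure of the storage trial the method was
designed around and are not tuning knobs.

**Design.** Origins MI and SAMS; harvest years 2019–2021 (MI) and
2019–2020 (SAMS); storage temperatures per origin/year mirroring the trial
(e.g. 0/5/10/15 °C for the 2020 harvests); sampling days 0–7; 4 replicate
samples per point (364 samples total).

**Growth.** The trial data come with no fitted kinetic model, so
trajectories use a logistic curve in log10 counts with a lag phase,
y(t) = nmax / (1 + ((nmax − n0)/n0)·e^(−μ(t−lag))), whose specific rate
follows the Ratkowsky square-root law μ(T) = (b·(T − Tmin))². Initial
loads n0 are the observed day-0 counts per origin/year (1.8–5.1 log
CFU/g); carrying capacities are 9.0–9.8; b = 0.065 and Tmin = −5 °C were
chosen once so 0 °C storage is nearly flat while 15 °C saturates by day
3–4, as observed. Replicate noise is Normal(0, 0.4 log CFU/g), typical of
the trial's replicate SDs, and simulated counts are floored at 1.0 log
CFU/g — the plate-count detection limit visible in the trial's tables.
These parameters are calibration targets for the simulator, not claims
about the real organisms.

**FT-IR forward model.** spectrum = scatter × (baseline + Σ amplitude ×
Gaussian) + noise on the 4000–400 cm⁻¹ grid at 1 cm⁻¹. Bands sit at the
wavenumbers where spoilage chemistry is visible — lipid esters (1745),
amide II (1548) and carbohydrates (1156/1074/1043) with negative TVC
coefficients (substrates consumed), primary alcohols (1020) positive
(metabolites produced) — plus a large TVC-blind water band (1637) and
origin/year nuisance bands (1260, 1220, 1410). The baseline is a gentle
second-order polynomial; scatter is log-normal (σ = 0.15) so RNV
demonstrably removes it; additive noise σ = 0.005 absorbance.

**MSI forward model.** Band means are a brown-seaweed-like reflectance
profile plus a per-origin/year colour shift (σ = 0.08, acting mainly on
the visible bands ≤ 700 nm) plus a weak TVC coupling (0.004 per log,
mainly NIR) and noise; band SDs grow slightly with TVC. Harvest identity
dominates by construction, which is exactly why the MSI pipeline
underperforms FT-IR here.

**E-nose forward model.** Each sensor's response is gain × amplitude ×
f(TVC) + noise, with f a logistic in TVC (midpoint 6 log CFU/g, scale 1.2)
that decays for the ten "fresh-stronger" sensors and rises for the two
metabolite-tracking sensors (ethanol and amine channels); MI gain 1.2 vs
SAMS 0.8 reproduces the origin asymmetry. Values are emitted through the
(R − R₀)/R₀ definition.

**What passing tests do and do not show.** The generator reproduces the
structure of real data — growth kinetics, band chemistry with the right
signs, nuisance-dominated colour, origin-scaled volatile response — but
not instrument line shapes, absolute absorbance units, detector drift,
pixel-level images or temperature-dependent water-band shifts. Recovery
results on synthetic data (held-out R² ≥ 0.9 for FT-IR, selected
wavenumbers concentrating near truly informative bands, FT-IR > MSI
ordering) validate the pipeline's machinery, not its performance on any
particular real instrument.

## Determinism and problem sizes

Every stochastic step (replicate noise, all sensor noises, splits, CV
repartitions, boosting, EM restarts) draws from seeded generators; the
generators derive independent child streams from the configured seed, so
reruns are byte-identical down to the serialized model documents. The test
suite and the acceptance script run the full pipeline at the study's
natural scale (≈360 samples × 1800 retained wavenumbers, 100 boosting
cycles, 10×10 cross-validation), which completes in a few minutes on a
single CPU; unit tests use smaller designs (fewer sampling days and
replicates) where the property under test does not depend on scale.

## Known limitations

* Mixtures beyond two components, multivariate mixtures and recursive
  feature elimination are out of scope, as are multi-response PLS,
  orthogonal-signal-correction variants and nonlinear kernels.
* Vendor binary formats are not parsed; I/O is plain wide CSV.
* The bimodality screen assumes the sampled trial actually spans fresh and
  spoiled states; applied to a narrow-TVC dataset it will correctly but
  unhelpfully reject everything.
* Feature selection outside the CV loop means internal CV metrics can be
  optimistic; external validation splits are the honest yardstick.
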