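# Methods

This note records the models, parameter choices and numerical conventions
behind `fluxgap`, and what the synthetic test bed does and does not show
about real tower data.

## The synthetic world

Everything downstream is evaluated on synthetic half-hourly years whose
generating process is known exactly, so any discrepancy between a filled
and a complete series is attributable to the filler.

**Radiation.** Clear-sky SWR is `S0 · τ^(1/cos z) · cos z` with solar
constant S0 = 1361 W m⁻², broadband transmittance τ = 0.75 and spherical
solar geometry (declination ±23.44°, half-hour mid-point hour angles).
Cloudiness is a daily Beta-distributed fraction with lag-1 autocorrelation
0.6 (Gaussian copula), applied as a multiplicative factor
`1 − 0.9·cloud` plus 12 % within-day flicker. The Beta mean rises with
latitude (0.42 + 0.0045·|lat|, concentration 1.5): boreal maritime
climates are cloudier, and the near-bimodal clear/overcast alternation is
what gives the annual daytime SWR distribution its strong right skew. At
the defaults the daytime skewness is ≈ 1.2 at 35°N and ≈ 1.7 at 65°N and
increases monotonically in between — the property the sampling-bias
mechanism needs. These are package choices: the generator is a statistical
stand-in for measured drivers, not a weather model.

**Temperature, VPD, soil temperature.** Air temperature is an annual
sinusoid (mean 4 °C, semi-amplitude 13 °C, minimum mid-January) plus a
diurnal cycle (6 °C peak-to-trough, damped under cloud) and AR(1) weather
noise; VPD follows from a Magnus saturation curve with relative humidity
increasing in cloudiness; soil temperature is a ~10-day exponential
moving average of air temperature.

**Truth NEE.** `NEE = R − GPP` with Q10 respiration
`R = r10·q10^((T−10)/10)` (r10 = 2.2 µmol m⁻² s⁻¹, q10 = 2.1) and a
rectangular-hyperbola light response
`GPP = season(doy)·P_max·SWR/(k½+SWR)·exp(−s·VPD)` with
P_max = 18 µmol m⁻² s⁻¹, k½ = 170 W m⁻², s = 0.015 hPa⁻¹ and a smooth
logistic growing season (onset day 115, decline day 280, 14-day ramp).
The initial slope P_max/k½ ≈ 0.1 µmol per W m⁻² of global radiation and
the asymptote are at the scale of boreal evergreen canopies. Only two
properties of this model carry the analysis: GPP is concave in SWR, and
NEE(SWR = 0) is pure respiration.

**Noise.** Per-record residuals are Laplace-distributed (flux random
error is observed to be heavy-tailed) with standard deviation
`0.6 + 0.25·|NEE|` µmol m⁻² s⁻¹, the middle of the range reported for
forest eddy-covariance sites. Residuals are pooled into 20 bins — season
(winter = months 1–4, 11–12; summer = 5–10) × time of day (night =
SWR ≤ 20 W m⁻²) × five equal-count air-temperature bins — and each
record's noise is drawn with replacement from its own bin, so the
injected noise is heteroscedastic in exactly the binned sense. Bins that
no record maps to (winter nights never reach the warmest temperature
quintile at boreal sites) are left empty by default; `inject_noise`
raises if a record ever maps to an empty pool, and
`fit_noise_model(..., require_all_bins=True)` enforces full coverage for
users who need it.

**ANN surrogate.** For building synthetic years from real files,
`fit_truth_surrogate` trains a sequential network with hidden layers of
16, 32, 32, 32 units and activations linear–tanh–tanh–relu (linear
output) on all measured records, inputs (tair, tsoil, SWR, VPD) and the
target standardised, MSE loss. Training is mini-batch Adam (batch 256,
learning rate 10⁻³, 300 epochs by default) implemented directly on
numpy; these training settings are package defaults, chosen so that a
smooth driver-only generating function is recovered to ≈ 1–2 % of the NEE
standard deviation from one year of data. Note the package's default
truth model is *not* exactly recoverable by the surrogate: its seasonal
switch depends on day of year, which is not among the four predictors, so
a ≈ 7 % residual remains — the same identifiability limit applies to any
regressor on those four drivers.

## Gap model

Artificial gaps are drawn from a catalogue of (length, start
time-of-day) pairs — extracted from a real file's missing-data runs
(runs longer than 3 days are excluded; only 0.5 h–3 day gaps are ever
inserted) or from a bundled synthetic catalogue with night-weighted
start slots (3:1) and a geometric length tail capped at 144 half hours.
Insertion draws entries with replacement, places each gap on a uniformly
chosen day *at its retained start slot*, rejects placements that
overlap, run off the series or cover non-measured records, and stops
when the masked fraction reaches the target (overshoot < one gap
length). `gap_fraction` means the fraction masked: the 30/50/70 % classes
mask 30/50/70 % of the records. The plan records each inserted gap, so
timing diagnostics compare inserted start slots with the catalogue
directly; at gap fractions ≳ 0.5 rejection sampling measurably flattens
the slot distribution (popular night slots fill up first), which is a
property of non-overlapping placement, not a bug.

Two exhaustive labellings support method evaluation: leave-one-out (one
single-record plan per measured record — the natural unit for a lookup
method) and 100 random disjoint ~1 % folds (for the boosted filler, where
one model per record would be wasteful). Fold assignment is random, not
contiguous.

## MDS

Tolerances: SWR 20 W m⁻² at gap-SWR ≤ 50 W m⁻² and 50 W m⁻² above (ties
at exactly 50 take the low band), tair 2.5 K, VPD 5 hPa. If tair or VPD
is missing at the gap only SWR is used; if SWR is missing too, only the
mean diurnal course. The window cascade is configurable and defaults to:
all-driver ± 7 and ± 14 d; SWR-only ± 7 d; MDC (same slot ± 1 h, i.e.
± 2 half-hours, wrapping midnight) at ± 0, ± 1, ± 2 d; all-driver
widening by 7 d to ± 70 d; SWR-only widening to ± 70 d; MDC widening to
± 210 d. The first step with at least `min_sample = 2` candidates wins
("sufficiently large" is not standardised; 2 is the smallest sample with
an average). Gaps that survive the whole cascade are flagged unfilled,
never imputed as zero. Fill provenance (cascade step, sample size) is
kept per record and exported as a QC-like tier column.

Variants: `narrowed` = tolerances [10, 25]; `single_tol` = one 25 W m⁻²
tolerance everywhere; `subsample_mean` = for daytime gaps
(SWR ≥ 20 W m⁻²) average the mean NEE of the below-target and
above-target SWR subsamples — candidates at exactly the target SWR join
neither subsample, and single-sided or nighttime cases fall back to the
plain mean. The variant acts only at the similarity tiers (MDC has no SWR
conditioning).

Two day/night constants coexist deliberately: noise binning treats
SWR ≤ 20 as night, evaluation treats SWR ≥ 20 as day; both are exposed
as parameters.

The inner loop is a numba kernel that accumulates sums in ascending
index order; the test suite pins it, bit for bit, to an independent
pure-Python scan that applies the predicates literally.

## Boosted-tree filler

XGBoost regression (squared error, `tree_method=hist`, single thread,
fixed seed) on eight features: SWR, tair, VPD, the cyclic encodings
t₁ = sin((month−1)·2π/12), t₂ = cos(·), t₃ = sin(hour·2π/24),
t₄ = cos(·) and the half-hour index t₅. Hyperparameter selection runs a
full grid — column subsample {0.4, 0.6, 0.8, 1}, max depth {3, 5, 10,
15}, minimum observations per new node {2, 5, 10} (mapped to
`min_child_weight`, exact under a squared-error hessian of 1), row
subsample {0.65, 0.75, 1} — per dataset against a 25 % random holdout,
then takes the per-hyperparameter mode across datasets (ties → smaller
value). Learning rate is 0.1. The number of boosting rounds is not
standardised anywhere; the package default is 200 with no early
stopping, and the experiment driver uses 100 (the ranking against MDS is
insensitive to this, and it halves the benchmark cost).

## Evaluation

Mean bias `Σ(NEE_fill − NEE_ref)/N` and RMSE are computed over masked
records only, optionally split at SWR ≥ 20 W m⁻² (day). The annual
balance error converts each half-hourly difference by
1800 s × 12.01 × 10⁻⁶ g µmol⁻¹ = 0.021618 g C per unit flux; because
unmasked records are identical in the filled and reference series, the
year sum equals the masked-record sum exactly (asserted to 10⁻⁹
relative). Sample bias is the signed count excess of below-target over
above-target SWR candidates; SWR skewness is the adjusted Fisher–Pearson
estimator (all hours by default, daytime subset optional — total-series
skewness is inflated by the night mass at zero, so the two are reported
separately).

Replicate-level inference: exact two-sided Wilcoxon signed-rank for
median ≠ 0 with a Shapiro–Wilk normality screen reported alongside
(all-zero inputs return p = 1, flagged; < 5 replicates attach a power
warning); pairwise method comparisons use the Conover–Iman statistic on
joint Kruskal–Wallis ranks with Holm adjustment.

`run_experiment` crosses truth replicates (default 5) × gap fractions
(0.3, 0.5, 0.7) × gap-mask replicates (default 10, generated once and
shared across truth replicates and methods, so comparisons are paired on
identical masks) × methods, and emits one long-format row per cell.
Every sub-seed is spawned from the master seed; a rerun is bit-identical.
Summaries report the median balance error per method × fraction
(medians, not means — balance-error distributions are skewed) and
day/night bias and RMSE at the largest gap fraction.

## What the tests do and do not show

The synthetic world reproduces the *structure* that makes lookup-table
gap-filling biased at northern sites — skewed radiation sampling against
a concave light response, night-heavy gap timing, binned heteroscedastic
noise. At the defaults (62°N), standard MDS shows a leave-one-out
daytime bias of ≈ +0.2 µmol m⁻² s⁻¹, a much smaller negative nighttime
bias, and median annual balance errors of roughly +4 to +10 g C m⁻² y⁻¹
across the 30–70 % gap classes, with the boosted filler near zero — the
magnitudes real northern sites exhibit. It does not emulate u*-filtering
physics, instrument failure modes, storage-flux artefacts, advection, or
driver measurement error; absolute error magnitudes on any real site
depend on its own light response, noise level and gap climate, so the
package's numbers characterise the mechanism, not a specific tower.
Leap years are supported; all per-year arithmetic uses the actual record
count.
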