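# Methods

## Signal container and ingestion

The universal container is `RRSeries`: strictly positive R-R intervals in
milliseconds with derived beat end-times `t_end_s[i] = Σ_{j≤i} RR_j/1000`.
Beat *i* occupies the half-open interval `(t_end[i−1], t_end[i]]`, which
makes window assignment deterministic at boundaries. The text dialect is
one interval per line; a single leading non-numeric line is treated as a
header and skipped with a logged notice — consumer app exports are not
formally documented, so this is a tolerant guess rather than a format
specification. Physiological screening (mean HR in [40, 220] bpm, each
interval in [250, 2500] ms) only warns; artifact handling is a separate,
explicit step.

## Beat artifact correction

Detection: beat *i* is flagged when it deviates by more than 25 % from the
median of the 11-beat window centred on it (window truncated at the
edges, median **including** the beat itself — the median is robust to the
single candidate outlier, and self-exclusion misbehaves on very short
series where the artifact dominates a truncated window). Both the 25 %
threshold and the window length are configurable; they are conventional
strong-correction choices, not physiological constants, and the original
protocol corrected beats manually without a stated numeric rule, so this
detector is an explicit stand-in.

Correction is a single pass using original neighbour values (no cascade):
a `high` beat becomes the mean of its two adjacent original intervals
(single available neighbour at the edges, logged); a `low` beat becomes
the previous original interval (the next one at index 0, logged). Length
is always preserved. Single-pass correction is idempotent when artifacts
are isolated; two corrupted beats within each other's replacement
neighbourhood can leave a residually deviant replacement that a second
pass would adjust — the tests assert the conditional form.

Inclusion: a segment whose corrected fraction exceeds 20 % of beats is
excluded, applied per phase stream because phases are analysed
separately.

## Time domain

SDNN is the sample (n−1) standard deviation; RMSSD averages squared
successive differences over the n−1 pairs; NN50/pNN50 count differences
strictly greater than 50 ms; the RMSSD log transform is the natural log.
Mean heart rate is the mean of per-beat instantaneous rates 60000/RR_i
(the convention of the common analysis software), with 60000/mean(RR)
exposed as a secondary field; the two differ on variable series by
Jensen's inequality.

## Frequency domain

The tachogram (RR against beat end-time) is cubic-spline interpolated and
resampled at 4 Hz, linearly detrended, and fitted with an AR model by
Burg's method at order 16 (the common default of short-term HRV software;
configurable). The one-sided PSD is evaluated on a dense grid over
[0, 2 Hz] and integrated by the trapezoid rule over VLF 0.003–0.04, LF
0.04–0.15 and HF 0.15–0.40 Hz. Band edges are the adult short-term
conventions; children can breathe above 0.4 Hz, so the HF upper edge is a
config override (`SpectralConfig.with_hf_upper`), deliberately not a
different default. Total power is VLF+LF+HF; normalized units are defined
on LF+HF, so `lf_nu + hf_nu = 100` identically.

Numerical choices: the AR transfer function of a strongly periodic, low
noise tachogram has poles very close to the unit circle, producing peaks
too narrow for coarse grids — at 4097 grid points the LF/HF split of an
equal-tone construction is biased by ~5 normalized units, while at the
default 16385 points it is converged (identical to 2 decimals at 4× and
16× denser grids). A fit with a pole on or outside the unit circle raises
with advice to lower the order. A constant signal short-circuits to zero
power. Recordings under 60 s are refused (the protocol restricts 30 s
recovery windows to the time domain); under 240 s a warning notes the LF
estimate is not fully supported.

## Protocol segmentation and step test

Recovery onset is anchored at the end of the last stepping beat; the 2 min
recovery is split into four 30 s windows by beat end time with the
half-open rule `[30w, 30(w+1))`. A consequence worth stating: 240 uniform
500 ms beats split 59/60/60/60, because the beat ending exactly at 30.0 s
opens the second window and the beat ending at 120.0 s falls outside the
recovery span. Shorter streams yield as many complete windows as fit,
with a warning.

Age-predicted maximal heart rate uses the Tanaka estimate
MHR = 208 − 0.7·age, the most accurate age prediction in children;
step-test intensity is mean stepping HR as a percent of it. The VO2max
prediction equation is a registry hook (`register_vo2max_equation`)
rather than a built-in, and step height is a stature-keyed lookup table
supplied by the user — neither quantity has a canonical closed form the
package should hard-code.

## Reliability statistics

TEM = SD(difference scores)/√2; TEM% = 100·TEM/grand mean of all 2n
observations. TEM% and CV are one quantity with two names and are stored
once. The 90 % interval for TEM uses the chi-square distribution of the
error variance with df = n−1: `tem·sqrt(df/χ²_{0.95,df})` to
`tem·sqrt(df/χ²_{0.05,df})`; the interval for TEM% applies the same
scale-free multipliers. The exact spreadsheet convention behind published
TEM intervals varies, so agreement with any given table is expected only
to about the last printed digit.

Pearson r carries a Fisher-z interval with half-width 1.645/√(n−3);
perfectly correlated trials cap at (1, 1). Classification bins place the
boundary values 5 and 10 in "moderate" CV and 0.5/0.75/0.9 in the higher
r class; the conventional wordings are ambiguous exactly at the
boundaries, so the convention is fixed here.

The Fisher-z sample-size formula `n = ceil(((z_crit + z_power)/atanh r)² + 3)`
gives 17 (two-sided) or 15 (one-sided) at r = 0.70, α = 0.05, power 0.90.
A requirement of n = 13 sometimes quoted for those inputs is not
reproduced by this standard formula; the package implements the formula
and leaves the discrepancy flagged rather than matching the quote.

The paired t-test reports t = 0, p = 1 with a note when all differences
are zero, and refuses a constant non-zero shift (zero variance, undefined
t).

## Synthetic data: what it emulates and what it does not

The resting generator builds beats iteratively:
`RR_i = mean + A_LF sin(2π f_LF t_i) + A_HF sin(2π f_HF t_i) + N(0, σ²)`,
with `t` advanced by each interval. Defaults — 700 ms mean, 25 ms at
0.10 Hz, 35 ms at 0.28 Hz, 10 ms noise, 300 s — give a resting child's
heart rate with respiratory-dominant variability; 0.28 Hz reflects
children's faster breathing. The recovery generator is the first-order
vagal-reactivation model `RR(t) = end − (end−start)e^{−t/τ}`. Artifact
injection corrupts beats independently, multiplying (`high`) or dividing
(`low`) by 1 + magnitude, and returns ground-truth indices.

Sinusoidal modulation was chosen over integral-pulse-frequency-modulation
for transparency; IPFM, respiration–cardiac coupling, non-stationarity
and true ectopy morphology are not modelled. Passing tests therefore
demonstrate estimator correctness on signals with the assumed structure,
not robustness to every property of real paediatric recordings.

Paired cohorts draw subject true values `μ_j ~ N(mean, σ_b²)` and either
add `N(0, TEM²)` per trial (additive) or multiply by `exp(N(0, s²))`
(multiplicative). The log-scale SD is calibrated as
`s² = ln(1 + (cv/100)²/(1 + (σ_b/mean)²))`: the grand-mean-based TEM%
estimator is inflated by `sqrt(1 + (σ_b/mean)²)` under multiplicative
error, and this exact calibration makes the nominal CV equal the
population value of the estimand for any cohort geometry (it reduces to
the usual `s ≈ ln(1 + cv/100)` when between-subject spread is small).
With the additive form the implied test-retest correlation is
`σ_b²/(σ_b² + TEM²)`, and a cohort may equivalently be parameterized by
`true_r` instead of `σ_b`. All generators take explicit seeds; no global
RNG state is touched.

## Pipeline

`run_study` reads a manifest CSV (subject, anthropometrics, day, phase,
R-R file), corrects every phase stream, drops sessions failing the 20 %
criterion or missing rest/recovery (logged, recorded in the metadata),
computes resting time+frequency metrics and recovery-window time-domain
metrics, and assembles per-parameter reliability across subjects with
both days (aborting below 3 complete subjects). Recovery windows never
receive spectral columns — enforced, not optional. Outputs are CSVs, a
published-style Markdown table (`1.41 (1.07–2.08)` cells, em dash for
undefined), and `run_metadata.yaml` listing every default and decision
value so a rerun with the same config is bit-identical.

## Problem sizes in the checks

The verification suite uses 100 000-subject cohorts for parameter
recovery (TEM within 1 %, CV within 0.2 percentage points), 2000
simulated n = 14 cohorts for 90 % CI coverage (±2 points), 1000 random
series against a brute-force two-loop time-domain oracle (1e−9 relative),
and 300 s single-tone tachograms for the spectral checks. These sizes
make the stochastic assertions tight while keeping the full suite fast on
one CPU.

## Known limitations

Frequency-domain results depend on decisions the protocol leaves open
(AR order, resampling rate, detrending, band edges); all are recorded in
run metadata but defaults follow adult conventions. The artifact detector
is a numeric stand-in for manual editing. Geometric HRV indices, Poincaré
measures, ICC and Bland–Altman agreement are deliberately out of scope.
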