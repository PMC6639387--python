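# Methods

## Problem and scope

`eegslow` implements a complete analysis chain for resting-state, eyes-closed
prefrontal EEG slowing as a correlate and predictor of global cognition:

1. two-channel (Fp1/Fp2) EEG at 250 Hz, 5 min per subject;
2. three spectral slowing biomarkers — median frequency (MDF), peak
   frequency (PF) and alpha-to-theta ratio (ATR);
3. association statistics against MMSE stage, total and domain scores;
4. penalized-regression prediction of the MMSE total with double
   cross-validation.

Because cohort-scale raw EEG of this kind is generally not deposited, the
package ships a synthetic generator whose outputs have the statistical
structure the analysis assumes; every stage is exercised end-to-end on
generated data.

## Signal model and spectral conventions

**Acquisition filters.** The amplifier front end is modelled as three causal
digital IIR Butterworth filters: band-stop 2nd order with edges 55 and 65 Hz,
high-pass 1st order at 2.6 Hz, low-pass 8th order at 43 Hz. Filters are
implemented as second-order sections and applied forward-only by default
(they describe a real-time device); zero-phase forward-backward filtering is
available as an option. The design requires fs > 130 Hz so the stop band
stays below Nyquist.

**Periodogram.** A single full-length rectangular-window periodogram of the
mean-removed signal, one per channel, with one-sided scaling chosen so the
bin powers sum to the signal's mean square (Parseval, tested at 1e-8
relative). No Welch segmentation or tapering: the protocol specifies a plain
FFT over the whole record, and the biomarkers are integral quantities that
do not need variance reduction. Resolution is fs/N (3.3 mHz for a 5-minute
record).

**Band conventions.** Bins are half-open: theta = [4, 8) Hz, alpha =
[8, 13) Hz, dominant band = [4, 13) Hz, so the two sub-bands partition the
dominant band and no bin is counted twice.

**MDF** is computed by the two-step rule: halve the summed 4–13 Hz power,
then take the first bin (ascending) whose cumulative power *strictly*
exceeds that half-total. The strict inequality matters only for exact ties
(a bin reaching exactly half does not qualify); it is frozen by a
brute-force cumulative-sum oracle test. **PF** is the in-band argmax with
ties broken to the lowest frequency (deterministic, and conservative in the
slowing direction). **ATR** is the linear power ratio P_alpha / P_theta,
computed as exp of the difference of the natural-log band powers. A ratio of
the log powers themselves would be unit-dependent, which contradicts ATR
being a unitless power ratio with values of order 1; the log-power route is
kept because the band powers are reported on the natural-log scale.
A zero band power yields a -inf log sentinel rather than an exception, so
degenerate spectra stay representable in reports.

**Channel averaging** is of the biomarker values, not the spectra: MDF, PF
and ATR are computed per channel and arithmetically averaged.

**Artifact handling** is report-only: the screen computes the fraction of
samples whose magnitude exceeds 200 µV (also 150 and 100 µV for reporting)
and fails a recording only if the fraction strictly exceeds 10%, but nothing
is rejected automatically — mirroring a protocol in which no recordings were
discarded. A separate utility finds the earliest one-minute slice in which
both channels stay within ±80 µV, used to demonstrate that slice and
full-record biomarkers agree on clean data.

## Synthetic data

**EEG.** Per channel: an alpha sinusoid at `peak_freq` (5–12 Hz) with random
phase and slow (<0.5 Hz) amplitude jitter; a theta component realized as
narrowband Gaussian noise within ±1 Hz of `theta_freq` (6 Hz default) with
RMS matched to a sinusoid of amplitude `theta_amp` — a band rather than a
line, so the dominant spectral peak remains the alpha rhythm; and a 1/f
("pink") background synthesized by spectral shaping of white Gaussian noise
(exact −1 log-log power slope, testable). The two channels share the
oscillatory sources and mix shared/independent pink-noise streams to a
channel correlation of about 0.8, reflecting how close Fp1 and Fp2 are
physiologically. Optional artifacts: bilateral half-sine blinks (0.2–0.5 s,
100–400 µV) and unilateral 20–43 Hz EMG bursts (0.3–1 s, 30–80 µV RMS),
Poisson-distributed at per-minute rates, all logged as events. Defaults
(alpha 18 µV, theta 12 µV, pink 10 µV RMS) put the extracted biomarkers in
the typical eyes-closed prefrontal range (MDF ≈ 8.5 Hz, ATR of order 1).

**Cohort.** One latent "slowing" scalar per subject, standard normal with a
−0.45 loading on standardized age, drives all three biomarkers jointly
(affine maps with independent jitter, calibrated to MDF 8.5 ± 0.9 Hz,
PF 8.7 ± 1.3 Hz, ATR geometric mean 1.26 with ~25% scatter, clipped to the
plausible measurement ranges). Age is truncated normal 68 ± 10 on [50, 90];
education is integer years on [0, 18], declining with age; sex is Bernoulli
with 2/3 female. The MMSE total is `mmse_base` (25) plus a linear
combination of standardized predictors (defaults: MDF +1.5, age −1.6,
education +1.6, sex −0.2, chosen once to reproduce the qualitative
correlation pattern of such cohorts: corr(MMSE, MDF) ≈ 0.5,
corr(MMSE, age) ≈ −0.6) plus Gaussian noise with SD 2.7 points — the
irreducible-error scale this kind of model reaches — rounded and clipped to
[0, 30]. Domain scores are allocated proportionally to the standard domain maxima
(5, 5, 3, 5, 3, 6, 1, 2) by largest-remainder rounding with the remainder
assigned in a fixed priority order starting at orientation to time (the
domain most associated with slowing); scores always sum to the total and
respect the maxima.

What the generator does *not* emulate: drowsiness and vigilance drift,
eyes-open contamination, non-stationary alpha splitting, realistic MMSE
item-level response processes, and floor/ceiling psychometrics beyond
clipping. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline*, not clinical performance on real recordings.

## Statistics

* Pearson correlations use Fisher-z confidence intervals; Bonferroni
  adjustment multiplies p by the number of tests m (capped at 1) and widens
  intervals to the simultaneous 1 − α/m level.
* Partial correlations are residual-based (x and y regressed on the
  covariates with intercept), p on n − 2 − k df, interval at effective
  sample size n − k. Verified against the one-covariate closed form and an
  independent implementation.
* Independent-group comparisons (female vs male): Fisher Z test with Zou's
  modified-asymptotic interval for r1 − r2 (combining the individual
  Fisher-z intervals). Dependent comparisons sharing one variable: the
  Meng–Rosenthal–Rubin Z with its interval reported on the Fisher-z
  difference scale (the scale on which the statistic is normal); the delta
  itself stays on the correlation scale. Both tests are calibrated by
  simulation (type-I error within ±0.01 of 0.05; Zou coverage within ±1% of
  95%).
* Stage contrasts: ordinary least squares of biomarker ~ stage * sex + age
  + edu (a Gaussian identity-link GLM; 8 parameters), marginal means at the
  whole-sample mean age and education (the standard estimated-marginal-means
  convention; per-sex means were a design alternative, not taken), and
  consecutive contrasts T2−T3 and T1−T2 per sex on n − 8 residual df with
  Bonferroni over the 4 contrasts. Verified against an explicit
  normal-equations oracle to 1e-8.
* Standardized regression: response ~ biomarker + sex + age + edu; β* = β ·
  SD(x)/SD(y), p on n − 5 df.
* ICC is the two-way absolute-agreement single-measure form ICC(A,1) — the
  meaningful contract both for site interchangeability and model agreement,
  where systematic offsets must count against agreement; a consistency form
  would hide them. Bootstrap CI resamples subjects (percentile, fixed
  seed). Verified against variance-components ground truth and an
  independent implementation.
* Bland–Altman: differences true − predicted, LOA = mean ± 1.96 SD, with
  the standard approximate CI SE(LOA) = SD·sqrt(1/n + 1.96²/(2(n−1))).
* The paired t test returns NaN t/p for zero-variance differences
  (degenerate) rather than raising, so identical vectors report a mean
  difference of 0.

## Predictive modelling

Stages come from fixed cut points (T3: 28–30, T2: 25–27, T1: ≤ 24), not
data-driven tertiles. Continuous predictors are standardized on the
*training* split only (information hygiene; whole-sample standardization was
the alternative). The design is sex + {X, X², sex:X, sex:X²} for each of
MDF, PF, ATR, age, education — 21 columns plus an unpenalized intercept;
squares are of the standardized values. This single interacted model is what
produces sex-specific reference equations that share some coefficients (the
interaction being zeroed by the L1 penalty leaves the main term shared).

The elastic-net objective is (1/2n)·RSS + λ(α‖β‖₁ + (1−α)‖β‖₂²/2) with
internally standardized columns — the convention of the reference penalized
regression software, which also makes selected λ of order 10⁻³–10⁻²
natural. λ takes 300 log-spaced values from 10 down to 1e-4; α runs 0 to 1
in 0.1 steps (ridge/elastic net/LASSO; 3,300 candidates). Solutions are
checked against the ridge closed form, the λ_max = max|Xᵀy|/n KKT
threshold, the unpenalized limit at λ=0, and full subgradient optimality to
1e-6. Within the cross-validation loop the whole λ path per (fold, α) is
computed with a Gram-precomputed coordinate-descent path (ridge via
eigendecomposition), which is what makes the 33,000 fold-level fits cheap;
path solutions at the very smallest λ stop at the solver's default duality
gap, which is irrelevant for RMSE ranking and silenced.

"Ordinary weighted least squares" is implemented as least squares with unit
weights and an exposed `weights` argument, since no weighting scheme is part
of the protocol; a both-directions stepwise AIC search from the full model
is available for model reduction. Inside CV the WLS candidate is the full
21-term unit-weight model; the stepwise-reduced variant is fit once on the
full training set.

The 80/20 split and the 10 folds are stratified by stage; per-stratum test
counts use floors with the remainder assigned to the largest strata, so a
496-subject cohort splits 397/99 or 396/100 depending on stage sizes. Split,
fold and bootstrap seeds are separate configuration keys. Test-set metrics
(RMSE, Pearson r with CI, mean difference ± SD, 1000-rep bootstrap ICC,
Bland–Altman LOA) are computed once, after selection. Predicted MMSE is not
clipped to [0, 30] by default (agreement statistics should see the raw model
output); clipping is a one-liner for deployment use.

The reference final per-sex LASSO polynomials are encoded verbatim in
`prediction.FINAL_EQUATION_MALE/FEMALE` and evaluated by
`predict_final_equation` on the standardized scale.

## Numerical choices and degenerate inputs

* Periodogram requires ≥ 1 s of finite samples; MDF/PF require ≥ 2 bins and
  positive power in 4–13 Hz.
* Screen failure is strict (> 10%), so a fraction of exactly 0.10 passes.
* The clean-slice search scans candidate starts (0 and one past each
  out-of-bound sample) and returns an explicit "not found" result instead
  of raising.
* Constant columns cannot be standardized (error); collinear covariates and
  rank-deficient designs raise.
* EDF output quantizes to 16 bits over ±393 µV (≈ 0.012 µV steps) and whole
  1 s records; CSV round-trips exactly (round-trip float parsing).
* All generators use `numpy.random.default_rng` with explicit integer
  seeds; a fixed seed gives bit-identical outputs including the pipeline's
  output files.

## Problem sizes used in the shipped tests

Test and acceptance runs use synthetic cohorts of 80–500 subjects, EEG
records of 90–300 s, 50 pipeline replicates for parameter recovery, and
5,000–10,000 Monte-Carlo replicates for test calibration — sizes chosen so
the full suite demonstrates each property with comfortable statistical
margins while remaining quick to run on a laptop.

## Known limitations

* The synthetic cohort reproduces the qualitative co-movement of biomarkers,
  demographics and MMSE, not the real joint distribution; effect sizes are
  defaults, not calibrated to any real sample.
* Only the three slowing biomarkers are implemented — no connectivity,
  complexity/entropy or time-frequency measures, and no ICA-style ocular
  artifact removal.
* The Meng interval is on the Fisher-z difference scale; users wanting an
  r-scale interval for dependent differences should bootstrap.
* Single-equation GLMs only: no mixed effects, imputation or survey
  weights.
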