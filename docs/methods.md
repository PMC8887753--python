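# Methods

This note documents the models, defaults and numerical choices behind
`fhrv`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

An RR recording is a sequence of beat times t_k (s) and intervals rr_k
(ms) with t_{k+1} − t_k = rr_{k+1}/1000. Artifact detection is a single
forward pass: interval k is flagged when |rr_k − ref| exceeds the
threshold (default **40 ms**, per-recording override **100 ms** for noisy
recordings), where *ref* is the most recent accepted interval — a flagged
interval does not update the reference, so one spike cannot drag its
normal successor into the flagged set. Flagged intervals are replaced by a
cubic spline fitted to the accepted (time, RR) points; beat times are then
rebuilt from the corrected intervals. The spline abscissa is beat time,
not beat index, so runs of removed beats do not distort the interpolant.
Flagged runs at a boundary with fewer than two accepted neighbours on one
side fall back to nearest-neighbour replacement with a warning.

The quality gate requires, per analysed window, strictly fewer than 5 %
corrected intervals **and** strictly fewer than 5 successive corrections.

Detrending uses the smoothness-priors operator

    detrended = z − (I + λ² D₂ᵀ D₂)⁻¹ z,

with D₂ the (N−2)×N second-difference matrix and **λ = 500**, solved
exactly as a sparse SPD system (boundary rows included). The operator acts
as a time-varying high-pass filter; its time-invariant interior behaviour
has squared magnitude (g/(1+g))², g = 16λ²sin⁴(πf/f_s). `cutoff_frequency`
builds the operator on a 1024-point grid, evaluates the interior-row
response by FFT and refines the half-power crossing by root bracketing;
at λ = 500 and f_s = 4 Hz this gives ≈ 0.035 Hz. The same λ applied in
the beat domain (before SDNN/RMSSD) inherits an effective cutoff that
depends on the mean RR; this is documented behaviour, not hidden.
Whether time-domain metrics should be computed on detrended or raw
corrected intervals is genuinely open in practice (the common desktop HRV
workflow detrends); both modes are supported and **detrended is the
default** (`PipelineConfig.detrend_time_domain`). Mean RR always comes
from the un-detrended corrected intervals.

For spectral analysis only, RR is interpolated by a cubic spline onto a
uniform **4 Hz** grid spanning the segment.

## Pattern classification

RR is converted to bpm (60000/rr) on the 4 Hz grid. The floating baseline
is estimated in two passes: a centred 60-s running median (window
shrinking at the edges); then samples deviating ≥ 15 bpm from pass 1 —
candidate accelerations/decelerations — are excluded, the median re-run on
the remainder, gaps interpolated, and the result smoothed by a 15-s moving
average. The 60-s median window is robust to excursions up to roughly half
its length; the window length is a parameter (`median_win_s`) for traces
with longer plateau accelerations.

Excursions are maximal runs with |bpm − baseline| ≥ **15 bpm**; they
qualify as accelerations/decelerations when they last ≥ **15 s**.
Oscillation bandwidth is half the 2.5–97.5 percentile span of
(bpm − baseline) in the window, with qualifying-excursion samples
excluded; percentiles rather than min/max keep single samples from
inflating the bandwidth (for a pure sinusoid of half-amplitude a the
estimate is ≈ 0.96 a).

Window labels (non-exclusive; a window may carry several):

| label | criteria |
|---|---|
| SHRP | no qualifying excursion overlaps the window; baseline drift (max−min of baseline over the 120-s span centred on the window, clipped at recording edges) < 10 bpm |
| HRP I (GA 24⁺¹–32⁺⁰ wk only) | mean FHR < 160 bpm; drift over the 180-s centred span < 10 bpm; bandwidth < 5 bpm; accelerations *isolated* |
| HRP II | bandwidth > 5 bpm; FHR < 160 bpm outside qualifying accelerations |
| HRP III (GA 32⁺¹–41⁺⁶ wk only) | bandwidth > 10 bpm; *frequent, long-lasting* accelerations |

The qualitative terms are quantified as documented, configurable
constants: *isolated* = at most 1 qualifying acceleration in the
surrounding 10 min (none overlapping the window); *frequent,
long-lasting* = at least 2 qualifying accelerations of ≥ 30 s in the
surrounding 10 min. Drift is assessed on the estimated baseline over the
window-centred span (not any sub-span). The stationarity score of a
window is minus its 2-min baseline drift.

## Segment selection

Candidate windows of 64 s and 120 s slide at a 1-s step; each carries its
own within-window quality report and classification. Per recording, class
and length, the analysed pair is either the chronologically **first and
last** qualifying windows (HRP classes; an information-bias control) or
the **two most stationary** non-overlapping qualifying windows (SHRP
default; ties broken chronologically). Fewer than two non-overlapping
qualifying windows excludes the recording for that class/length with an
explicit machine-readable reason. Selection takes no HRV values as input,
so blinding to the outcome holds by construction.

## HRV parameters

Per segment (nine parameters): mean RR; SDNN (sample SD, N−1); RMSSD
(root mean square of successive differences); LF (0.04–0.4 Hz) and HF
(0.4–1.5 Hz) power in ms² plus LF/HF, under two estimators on the
detrended 4 Hz tachogram:

* **FFT path** — a single full-segment Hann-tapered periodogram (one
  window, zero overlap), zero-padded to ≥ 4× the segment length (next
  power of two), density-scaled with window-power compensation and then
  normalized so the trapezoidal integral over (0, f_s/2] equals the
  segment's sample variance.
* **AR path** — Burg's method at fixed order **24**; the PSD shape
  1/|A(e^{j2πf/f_s})|² is evaluated on 4096 frequencies and scaled so its
  integral equals the segment variance. Normalizing by shape rather than
  by the prediction variance keeps the estimator well defined for nearly
  noise-free inputs, where the prediction variance underflows while the
  pole structure (and hence the power allocation across bands) is intact.

Band powers are trapezoidal integrals with interpolated band edges; the
lower edge is inclusive and the upper exclusive, so 0.4 Hz belongs to HF.
LF/HF is reported as missing when HF integrates to zero.

## Reliability statistics

Each parameter is measured twice per fetus. On y = ln(value), the
balanced two-replicate random-intercept model has closed-form REML
estimates: σ̂²_E = Σd²ᵢ/(2m) from within-pair differences dᵢ, and
σ̂²_B = max(0, s²_means − σ̂²_E/2) from the variance of pair means (m−1
denominator), with the truncation at the REML boundary flagged in output.
The tests verify this closed form against an independent iterative REML
maximizer.

Derived statistics:

* within-subject CV = √(exp(σ²_E) − 1) — the exact log-normal form, not
  the first-order approximation σ_E (they differ < 1 % at the magnitudes
  involved);
* ICC = σ²_B/(σ²_B + σ²_E);
* Bland–Altman: bias = mean(d), 95 % LoA = bias ± 1.96·SD(d), both
  exponentiated to the ratio scale. SD(d) uses the ML (ddof = 0) form so
  the LoA half-width equals exp(1.96·√2·σ̂_E) exactly for zero-bias data,
  keeping the LoA and the variance components mutually consistent. The
  pair order is chronologically first minus second.
* averaging of n segments (n = 1…6): σ²_E → σ²_E/n, giving cv_n, icc_n
  and the 95 % prediction-ratio interval exp(±1.96·σ_E/√n). n = 1
  reproduces the base statistics identically.
* CV confidence interval: χ² limits on σ²_E with m degrees of freedom
  (m·σ̂²_E/σ²_E ~ χ²_m for the m independent within-pair contrasts),
  mapped through the CV formula.

Acceptability: CV ≤ 0.15 and ICC ≥ 0.80. Grouping: parameter × pattern
class × segment length, optionally × gestational-age group (A: 20⁺⁰–27⁺⁶,
B: 28⁺⁰–34⁺⁶, C: 35⁺⁰–41⁺⁰ weeks). Groups with < 3 complete pairs are
reported as *insufficient*. Outlying values (> 10× the group median) are
retained by default — they are treated as true measurements — with an
explicit sensitivity flag that drops their pairs instead.

The closed form covers the balanced two-replicate design; unbalanced
designs or > 2 replicates per subject are out of scope (the per-n block is
analytic extrapolation, not a fit).

## Synthetic data generator

`generate_rr_recording` emits beats iteratively, t_{k+1} = t_k +
rr(t_k)/1000, with

rr(t) = 60000/bpm_base(t) + a_LF sin(2πf_LF t + φ₁) + a_HF sin(2πf_HF t + φ₂) + ε,

ε ~ N(0, σ²). LF/HF modulation is additive **in milliseconds**, so each
sinusoid's band power is exactly a²/2 ms² — this is what makes the
spectral stages testable against analytic truth. Accelerations are
specified in bpm (the CTG convention) and converted through rr =
60000/bpm; their profile is a plateau with short cosine ramps, so an
event of amplitude ≥ 15 bpm and duration ≥ 15 s genuinely sustains the
qualifying deviation. Baseline drift is a bounded slow wander (600-s
sinusoid) whose steepest 120-s change equals the configured
`drift_bpm_per_2min`; a linear ramp at that rate over a 20-min recording
would sweep an unphysiological range. Phases are drawn per seed; a
fixed-phase option exists for exact regression tests.

Defaults emulate a quiet mid-gestation fetus: 20-min recording, baseline
RR 430 ms (≈ 140 bpm; the simulated cohort draws per-fetus baselines from
380–500 ms), drift 4 bpm/2 min, sparse 20-bpm/20-s accelerations, LF
modulation 5 ms at 0.1 Hz, HF 3 ms at 0.8 Hz, 3 ms beat noise, 1 %
artifact rate.

`inject_artifacts` corrupts a clean series with missed beats (two
intervals merged), ectopic beats (one interval split into a short/long
pair preserving total time) and spikes (± 60–200 ms); missed/ectopic
preserve cumulative time so the onset/RR invariant survives. Events are
placed on non-adjacent interior intervals so the ground-truth bookkeeping
(one recorded position per corrupted source interval) is exact.

`generate_paired_measurements` draws ln(value_ij) = μ + b_i + e_ij with
known σ_B, σ_E for variance-component recovery tests.

What the generator does **not** emulate: raw ECG waveforms and R-wave
detection errors at the waveform level, maternal ECG interference,
integral pulse-frequency-modulation beat timing, gestational-age trends in
HRV magnitude, fetal movement and behavioural-state dynamics, and
non-stationary spectra within a segment. Passing tests therefore certify
the numerics and decision logic of the pipeline, not its end-to-end
performance on clinical abdominal-ECG recordings.

## Problem sizes in the validation suite

The test suite favours the smallest sizes that still discriminate:
300-s single-purpose recordings for generator moments, 200 traces per
pattern kind for classifier fidelity, 200 simulation replicates at the
48-fetus design (plus one 1000-fetus run) for variance-component
recovery, 500 random datasets for the REML cross-check, and 1000 random
series for the time-domain oracle. The end-to-end orchestration tests use
6–12 recording cohorts.

## Known limitations

* The baseline estimator degrades when a single excursion approaches half
  the median window (60 s by default); widen `median_win_s` for recordings
  with very long accelerations.
* Burg AR(24) spectra of a *single* white-noise realization fluctuate by
  more than a factor 2 across the band; flatness holds for the ensemble
  mean. Band powers from the AR path on short (64-s) segments are
  correspondingly noisier than the FFT path.
* The HRP II/III qualitative criteria ("unstable baseline", "frequent
  accelerations") have no universally agreed quantification; the constants
  here are explicit and configurable, and results for those classes should
  be interpreted with that in mind.
* The 4-Hz tachogram attenuates HF components near the beat-rate Nyquist
  frequency (a 1.0-Hz modulation sampled by ~2.3-Hz beats loses power
  through interpolation); this is a property of beat-domain sampling, not
  of the spectral estimators, and affects any RR-resampling workflow.
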