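# fhrv — fetal heart-rate-variability reliability analysis

`fhrv` is a Python package for asking a deceptively simple question about
fetal heart rate variability (FHRV): *if you measure it twice in the same
fetus, do you get the same answer?* It implements a complete test–retest
pipeline for beat-to-beat fetal RR-interval recordings (e.g. from
non-invasive fetal ECG): artifact correction, detrending, CTG-style heart
rate pattern classification, paired segment selection, time- and
spectral-domain HRV parameters, and log-scale variance-components
reliability statistics. A synthetic recording generator with known ground
truth makes the whole chain testable without any clinical data.

It is aimed at researchers developing fetal monitoring methods and at
biostatisticians assessing whether an HRV parameter is reliable enough to
be used as a clinical measurement.

## The pipeline

1. **Preprocessing** — intervals deviating more than 40 ms (100 ms for
   noisy recordings) from the last accepted interval are flagged and
   replaced by cubic-spline interpolation. A segment qualifies only with
   < 5 % corrected intervals and < 5 successive corrections. Trends are
   removed by smoothness-priors regularization, detrended = z − (I +
   λ²D₂ᵀD₂)⁻¹z with λ = 500 (≈ 0.035 Hz cutoff at the 4 Hz resampling
   rate used for spectral analysis).
2. **Pattern classification** — RR is converted to bpm, a floating
   baseline is estimated, and accelerations/decelerations (±15 bpm from
   baseline sustained ≥ 15 s) are detected. Windows of 64 s or 120 s are
   labelled SHRP (stationary heart rate pattern: no qualifying excursions,
   baseline drift < 10 bpm per 2 min) or HRP I–III (Schneider-style
   criteria, gestational-age gated).
3. **Selection** — two non-overlapping qualifying windows per
   recording/class: chronologically first and last (HRP), or the two most
   stationary (SHRP). Selection never sees HRV values.
4. **HRV parameters** — per segment: mean RR, SDNN, RMSSD; LF
   (0.04–0.4 Hz) and HF (0.4–1.5 Hz) power and LF/HF under both a single
   full-segment Hann periodogram (FFT) and a Burg AR(24) spectrum.
5. **Reliability** — on y = ln(value), the balanced two-replicate
   random-intercept model y<sub>ij</sub> = μ + b<sub>i</sub> +
   e<sub>ij</sub>, b<sub>i</sub> ~ N(0, σ²_B), e<sub>ij</sub> ~ N(0, σ²_E)
   is fitted in closed form (REML). Reported per parameter × class ×
   length: within-subject CV = √(exp(σ²_E) − 1), ICC = σ²_B/(σ²_B + σ²_E),
   Bland–Altman 95 % limits of agreement on the ratio scale, and the
   analytic extrapolation to the mean of n = 1…6 repeated time series
   (σ²_E → σ²_E/n). Acceptable reliability: CV ≤ 0.15 and ICC ≥ 0.80.

## Worked example

Run the full pipeline on a simulated cohort of 12 fetal recordings
(≈ 20 min each, seeded, with baseline wander, accelerations, LF/HF
modulation and injected beat artifacts):

```python
from fhrv import PipelineConfig, run_pipeline

result = run_pipeline(n_synthetic=12, config=PipelineConfig(seed=42))
rel = result["reliability"]
print(rel[(rel["class"] == "SHRP") & (rel["length_s"] == 120.0)])
```

For the 120-s stationary-pattern segments this prints (abridged):

```
 parameter  n  median    cv  cv_ci_low  cv_ci_high  loa_low  loa_high   icc acceptable
hf_fft_ms2 12  13.478 0.179      0.128       0.299    0.799     1.715 0.812      False
mean_rr_ms 12 429.282 0.026      0.018       0.042    0.925     1.060 0.891       True
  rmssd_ms 12   7.011 0.027      0.019       0.044    0.959     1.086 0.979       True
   sdnn_ms 12   5.838 0.152      0.109       0.254    0.660     1.529 0.521      False
```

Reading the mean-RR row: across the 12 fetuses the two repeated 120-s
measurements differ by only 2.6 % (CV), 95 % of repeat ratios fall between
0.93 and 1.06 (LoA), and 89 % of the total log-scale variance is true
between-fetus variance (ICC) — mean RR is a reliable single-segment
measurement, while HF power and SDNN on this cohort are not (their CV
exceeds 15 %); averaging several time series (see
`reliability_per_n.tsv`) pushes them toward acceptability.

The same run from a shell:

```bash
fhrv run-all --n-synthetic 12 --seed 42 --out-dir out/
```

writes corrected RR series, window annotations, segment-pair manifests,
per-segment parameters and the reliability tables as plain CSV/TSV.

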