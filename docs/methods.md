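# Methods

This note records the models, parameter choices, and numerical decisions
behind `ppgq`, and what the synthetic data can and cannot establish.

## Signal model and filtering

A raw wrist reflectance PPG is treated as a large quasi-static baseline
(DC, arbitrary units, set by LED intensity and tissue absorption) plus a
small pulsatile component (AC, one pulse per heart beat) plus noise. Two
zero-phase IIR band-pass paths are used:

| path | design | band | purpose |
|---|---|---|---|
| SNR  | Chebyshev II, order 4, 20 dB stopband | 0.5–12 Hz | make the cardiac fundamental the dominant spectral peak |
| beat | Butterworth, order 4 | 0.5–8 Hz | stable beat detection and fiducial localisation |

"Order 4" is the designed order before forward–backward application; the
zero-phase pass squares the magnitude response (effective attenuation
doubles in dB). Edge transients are suppressed with odd-symmetric
reflection padding of length 3 × (realised order + 1). The
forward–backward pass is additionally **symmetrised** — averaged with its
time-reversed application — which makes filtering commute exactly with
time reversal (plain `filtfilt` differs at the edges by ~2% on 30 s
records) and halves residual edge transients. The 20 dB stopband
attenuation is configurable; it is a common choice for PPG work and its
exact value only affects out-of-band leakage.

Screening: a recording is `flat_line` when its maximum deviation from the
record median is below max(1e-6·|median|, 1e-12) or when >95% of
successive differences are exactly zero (a frozen channel), and
`too_short` below 10 s. Cohort screening is complete-case: a subject is
kept only if all 7 protocol recordings (2 supine + 5 sitting/standing
variants) exist and pass.

## SNR

The power spectrum is a single unaveraged periodogram with a Kaiser
window, β = 38 (strong sidelobe suppression; the harmonic/noise partition
is sensitive to leakage). The signal mean is removed before windowing:
a band-pass stopband only *attenuates* the large DC offset, and at 20 dB
attenuation the leaked offset's main lobe can otherwise out-power the
cardiac peak and mis-locate the fundamental.

Partition rules: the DC region runs from bin 0 while powers strictly
decrease; the fundamental is the global maximum outside it, its region
grown left and right while powers strictly decrease away from the centre;
harmonic regions are grown by the same rule around the nearest bin to
k·f₀ for k = 2..6 (configurable, never beyond Nyquist); all remaining bins
are noise. The four regions are disjoint and exhaustive, so their powers
sum to the total spectral power exactly. SNR = 10·log₁₀(P_fund/P_noise);
zero noise power reports +inf.

A consequence worth knowing: beat-interval variability spreads the
fundamental into sidebands that the monotone region rule assigns to noise,
so SNR falls with heart-rate variability even in noiseless signals. This
matches the behaviour of spectral SNR on real nonstationary PPG.

## Beat detection and fiducials

MSPTD: within a linearly detrended window, a sample is a scale-k local
maximum when it exceeds both neighbours k samples away; the scale d with
the most maxima is selected, and peaks are the samples that are maxima at
*every* scale 1..d (troughs analogously). Long records are processed in
6 s windows with 20% overlap; detections closer than 0.25 s are merged
keeping the larger-amplitude peak (smaller trough). The windowed path
degenerates to the exact whole-signal detector when the window exceeds the
record, and is verified against an O(n²) loop reference.

Between successive detections, the onset is the filtered-signal argmin and
the peak the subsequent argmax; the systolic-upslope mid-point is the
first sample reaching half of (onset + peak) amplitude — the conventional
half-rise fiducial (an interpretation: "mid-point" is read as amplitude,
not time). Boundary beats without flanking detections are dropped.
Amplitudes are then read from the original, unfiltered signal at those
indices; per-beat AC is floored at zero since baseline wander in the raw
signal can push peak-minus-onset marginally negative.

## TMCC

Window length = median inter-beat interval in samples, decremented to odd
so windows are symmetric about the mid-point sample; windows crossing the
record bounds are dropped; the template is the mean over *all* windows
regardless of quality; Pearson correlations use (n−1) normalisation and a
zero-variance window contributes 0. Fixed-length integer windows are used
(no resampling of individual pulses).

## Synthetic waveform generator

Each recording is `dc_level + wander + pulse train + white noise +
artifact bursts`:

* **Pulse kernel**: two Gaussians parametrised as fractions of one IBI
  (systolic at 0.22 ± 0.07, diastolic bump at 0.55 ± 0.12 with relative
  amplitude 0.3), scaled to the beat's own IBI so kernels never overlap;
  IBI deviations are truncated at 0.3 × mean IBI for the same reason.
* **Defaults**: fs = 100 Hz (comfortably above twice the 12 Hz analysis
  band), 30 s records, 70 bpm, beat-to-beat jitter 1.0 bpm (≈12 ms IBI SD,
  a low-HRV resting rhythm), DC 100 a.u., wander 0.1 a.u. at 0.2 Hz,
  white noise SD 0.03 a.u. Artifact bursts (Poisson arrivals, 0.5–2 s of
  brownian-like coloured noise) are off by default.
* **Condition effects**: the protocol conditions act on the pulse (AC)
  amplitude only — 0.76 a.u. supine down to 0.18 a.u. standing arm-down,
  matching typical observed per-condition perfusion-index medians — while
  the sensor noise floor is condition-independent. With these settings the
  simulated per-condition median SNRs span ≈9–19 dB with the supine >
  arm-up > lap > arm-down ordering. Jitter was kept at 1 bpm because
  larger values (≈3 bpm) floor the SNR near 5 dB for every condition and
  mask the amplitude gradient.
* **Subjects** get a Gaussian DC baseline shift (SD 10 a.u.); the cohort
  table's DC-amplitude covariate is the subject's realised DC level so
  waveform and covariate data stay consistent.

Ground truth carries beat onset times, per-beat noiseless AC amplitudes,
and per-component variances (pulse, wander, noise, artifact), so beat
detection, amplitude recovery, and power accounting are all testable
against known answers.

What the generator does **not** emulate: real pulse-wave morphology
changes (age-related dicrotic notch loss is parametrisable but not driven
by a physiological model), motion artifact with accelerometry structure,
hydrostatic/baroreflex mechanisms (posture effects are injected as
amplitude parameters, not simulated physiology), sensor quantisation, or
the six-figure DC counts of real devices. Passing tests therefore
demonstrate correctness of the *computations* under controlled conditions,
not performance on real wrist data.

## Metric-level cohort simulator

`simulate_metric_cohort` draws covariates from marginals matching the two
study-style cohorts (auscultatory-style: age 45 ± 13, 49.3% female,
BMI 28.7 ± 6.6, SBP 129 ± 19, DBP 78 ± 13, 8.4% diabetes, Fitzpatrick
types weighted 45/34/13/4/3/1%, DC amplitude a mixture of uniform bands
from 3k to 900k a.u.; oscillometric-style analogues), then sets
y = intercept + Σβx + b_subject + ε. Covariates are drawn independently
(no age–blood-pressure correlation), which slightly understates real
collinearity. Skin-tone missingness is parametrisable but defaults to
complete so covariate models retain all subjects. The default variance
components σ_b = σ_e = 4 dB are fixture choices on the SNR scale (the
source analysis reports none); they give intra-class correlation 0.5.

## Mixed-effects fitting

`fit_lmm` wraps statsmodels MixedLM: maximum likelihood (not REML),
subject random intercepts only, no random slopes (few repeats per
subject). Gender, diabetes, and skin type enter as numeric codes, matching
single-coefficient reporting. Rows with missing used columns are dropped
listwise with a logged count. Wald t-tests use residual degrees of freedom
n_obs − rank(X) (Satterthwaite/Kenward–Roger approximations are out of
scope); 95% CIs are estimate ± t_crit·SE. A rank-deficient design raises
an error naming the collinear columns; the pipeline (not the library)
responds by dropping constant or unidentifiable covariates on tiny demo
cohorts and logging the fact.

The 10-contrast family per metric is the union of four comparison groups:
natural arm positions across postures {standing arm-down, sitting lap,
supine} (3 pairs), heart-height positions {supine, sitting arm-up,
standing arm-up} (3), sitting heights (3), standing heights (1). Each
contrast is its own two-condition mixed-model fit; the 30 p-values form
one Holm–Šidák family (adjusted p = 1 − (1 − p)^(m−i+1) with a running
maximum, step-down rejection at α = 0.05).

For the posture/height factorisation, supine is coded height = arm-down
(the sensor lies alongside the body), giving treatment contrasts against
the standing posture and arm-down height reference levels.

## Problem sizes and determinism

The default pipeline demo uses 50 subjects (350 recordings, ~15 s end to
end); the parameter-recovery experiments in `scripts/acceptance.py` use
the published cohort sizes (499 and 643 subjects at the metric level,
seconds to fit). All randomness flows from one seed through
counter-based `SeedSequence` fan-out, so each stage is independently
reproducible and a repeated run is byte-identical.

## Known limitations

* The SNR's monotone-decrease peak regions slightly over-credit the
  fundamental (noise bins inside the peak region count as signal); the
  bias is < ~1 dB at 20 dB SNR and is shared by standard spectral-SNR
  implementations.
* TMCC windows are integer-length and unaligned in phase beyond the
  mid-point centring; strongly varying IBIs blur the template.
* The waveform simulator's quality gradient is an amplitude gradient;
  conclusions about mechanisms (hydrostatics, venous pooling) are outside
  its scope.
* With per-subject covariates only, covariate effects are identified
  between subjects; small cohorts (≲ 15 subjects) cannot support the full
  8-covariate model, which the pipeline handles by dropping terms.
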