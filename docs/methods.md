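# Methods

This note documents the models, estimators and numerical choices behind
`brainheart`, the assumptions they rest on, and what the synthetic-data
validation does and does not establish about real recordings.

## The heartbeat model (IPFM)

Simulated beat trains follow the integral pulse frequency modulation
model: with mean heart rate HR (beats/min) and a dimensionless
modulation m(t), a beat is emitted whenever

    Phi(t) = ∫₀ᵗ (1 + m(s)) · HR/60 ds

crosses an integer. The integral is accumulated by the trapezoid rule on
a 200 Hz grid and crossing times are found by linear inverse
interpolation within a grid step, giving beat-time accuracy well below
1 ms. m(t) is a sum of sinusoidal oscillators:

* an LF oscillator (default 0.1 Hz) and an HF oscillator (default
  0.25 Hz), each with a modulation depth (default 0.05) that may be
  slowly jittered by a smoothed Ornstein–Uhlenbeck (OU) process
  (`amplitude_jitter`, default 0.3 relative) — real HRV band power is
  not constant;
* during the paced-breathing epoch (first 188 s of intervention
  sessions) a respiratory sinusoid at 1/(inspiration + expiration)
  — 0.1 Hz for the 4 s/6 s protocol — with depth 0.1. Only the spectral
  location of this component matters downstream, so the asymmetric
  inspiration/expiration duty cycle is not modelled;
* white noise (sd 0.01).

Configurations are rejected when the total modulation depth could make
the instantaneous rate non-positive; the summed modulation is
additionally clipped at ±0.95 as a hard safety bound.

Free-breathing respiration outside the paced epoch is deliberately
unmodelled (it enters only through the noise term): the analyses
downstream read band power, not respiratory phase.

Synthetic ECG places a three-Gaussian QRS-like template (R wave sigma
8 ms with small Q/S lobes) at each beat time; it exists to exercise the
R-peak detector, not to mimic full P-QRS-T morphology.

## The EEG model

Each channel is 1/f background noise (unit exponent, 10 µV RMS,
FFT-shaped) plus a 10 Hz alpha sinusoid (5 µV) and a 20 Hz beta carrier
whose envelope e(t) is a rectified OU process (correlation time 2 s)
smoothed with a 2 s Hann kernel — a smooth, stationary, positive
envelope with tunable autocorrelation, shared across the midline
channels (midline beta is treated as one coherent source; per-channel
noise is independent). The carrier scale is 3 µV by default.

## Directional coupling in the generator

Scenarios are unidirectional by construction so estimates have an
unambiguous ground truth:

* brain→heart: the LF/HF oscillator amplitudes become
  a(t) = a₀ · (1 + g · ẽ(t − δ)), with ẽ the standardized envelope
  clipped at ±1.5 (bounding modulation depth) and δ the coupling delay
  (default 2 s, inside the 15 s analysis window);
* heart→brain: the envelope is multiplied by (1 + g · p̃(t − δ)), where
  p̃ is the standardized instantaneous oscillator power a(t)², and then
  renormalized to its pre-drive mean — the drive shapes the envelope's
  dynamics without changing mean beta power, so condition contrasts in
  band power are not confounded by the presence of coupling.

## Synthetic cohorts

`generate_cohort` creates participants with one intervention ("zen") and
one control session each, in randomized order. Responders' intervention
sessions carry descending (brain→heart) coupling (gain 1.2) plus
elevated LF (0.11) and HF (0.06) oscillator depths and a stronger beta
carrier (5 µV); their control sessions carry ascending (heart→brain)
coupling (gain 1.0) at baseline depths (LF 0.05, HF 0.045, beta 3 µV).
Non-responders have no coupling in either condition and only the LF
depth elevated in the intervention. This is the generative reading of
the study design the package targets: the intervention recruits
descending midline-beta control of cardiac rhythms in responders,
replacing the resting ascending influence, while non-responders show
only the breathing-driven LF rise. State-anxiety scores: baseline
uniform on 30–50; responders' decrement is round(k · R + ε) with R the
realized LF/HF amplitude-power ratio of their intervention session,
k = 3 by default and ε half-normal — anxiety reduction scales with the
realized autonomic shift; non-responders' scores stay equal or rise by
up to 2.

The oscillator depths were chosen so that genuine beat-to-beat
variability stays inside the IBI corrector's 25%-of-running-median rule
(successive-IBI changes < 25% at 70 bpm); deeper modulation makes the
corrector treat real dynamics as artifacts.

What the synthetic cohorts do **not** emulate: realistic ECG morphology
and noise fields, volume conduction and reference effects in EEG,
respiratory sinus arrhythmia transfer functions, movement/ocular
artifact morphology (only impulsive spikes are used for denoising
tests), free-breathing respiration, and between-participant variability
beyond seed-driven realization noise. Passing tests therefore establish
that the estimators recover what they claim from signals with the
designed spectral and coupling structure — not that they are robust to
every artifact class in real recordings.

## Cardiac processing

* Band-pass: zero-phase 4th-order Butterworth, 0.5–30 Hz (SOS,
  `sosfiltfilt`).
* Pan-Tompkins detection: 5–15 Hz band-pass, five-point derivative,
  squaring, 150 ms moving-window integration; adaptive signal/noise
  levels (SPKI/NPKI, 0.125 update) with threshold NPKI + 0.25·(SPKI −
  NPKI), search-back at half threshold when 1.66× the running RR has
  elapsed, 200 ms refractory; detected peaks are refined to the raw
  signal's local maximum within ±100 ms.
* IBI correction: an interval deviating more than 25% from the running
  median of the previous five accepted intervals (or outside
  [0.3, 2.0] s) is an artifact. Short intervals mark a spurious beat
  (removed); long intervals with round(dt/median) − 1 ≥ 1 mark missed
  beats, restored by cubic-spline interpolation of beat times over the
  beat index. Long-but-not-missed intervals (< 1.5× median) are genuine
  variability and pass through — inserting beats there was found to
  shred real modulation. All corrections are flagged; more than 20%
  corrected raises a warning (the quality level at which participants
  are typically excluded).

## The smoothed pseudo Wigner-Ville estimator

The corrected IBI series (ms) is cubic-spline resampled to 4 Hz
(Nyquist 2 Hz, far above the 0.4 Hz HF edge), mean-detrended and made
analytic (Hilbert). The discrete SPWVD is

    W(n, k) = Σ_m h(m) [ Σ_l g(l) x(n+m−l) x*(n−m−l) ] e^(−j2π(2m)k/N)

with a 127-sample Hamming lag window h (frequency smoothing) and a
61-sample normalized Hamming time window g, N = 2048, keeping the first
512 bins — a grid of 512 bins covering [0, 0.5) Hz with ~0.98 mHz
spacing at 4 Hz input. Residual negative values (cross terms that the
separable smoothing does not fully cancel) are clipped to zero; the
surface is scaled so the frequency integral approximates instantaneous
power (ms²). Smoothing windows are configurable; the defaults suppress
cross terms at the stated resolution. Peak locations are validated
against a Welch periodogram oracle across 0.05–0.3 Hz oscillators
(agreement within one bin).

Band integrals use rectangle sums over half-open bins (LF [0.04, 0.15),
HF [0.15, 0.4]), so the LF/HF partition of any spectrum supported on
[0.04, 0.4] is exact. Sliding-window series average the per-time-point
integrals over 1 min windows at 5 s steps; the LF/HF ratio is computed
per window on raw power *before* any normalization, then min-max scaled
like the band powers (the ratio values reported in normalized units
below 1 imply the ratio itself was scaled). Windows with zero HF
integral yield an undefined ratio (NaN) and are excluded from averages.
Min-max scaling pools min/max over both conditions of a participant, so
within-participant condition contrasts survive; window *centers* define
the 188 s breathing-epoch exclusion boundary, so no half-contaminated
window is kept.

## EEG processing

* Wavelet artifact suppression: per-channel multilevel Coiflet-3
  decomposition (level 6 at full rate, capped by signal length). Each
  detail level gets a universal threshold σ_j·√(2 ln N) with σ_j from
  that level's MAD/0.6745; coefficients are clipped at the threshold and
  the soft-thresholded excess — large transients such as ocular or
  movement artifacts — is reconstructed as the removed-artifact channel
  (denoised + removed = input exactly). Clipping the *large*
  coefficients, rather than shrinking the small ones, is what makes
  impulsive 20×-RMS artifacts recoverable (≥ 50% RMSE reduction in
  tests) while ongoing oscillations pass through; the classic
  keep-the-large-coefficients denoising convention provably cannot
  remove such artifacts.
* Filtering: 50 Hz notch (Q = 30) then zero-phase 1–48 Hz 4th-order
  Butterworth band-pass, in that order. Band extraction (when needed)
  uses a linear-phase Hamming-window FIR sized for a ≤ 2 Hz transition,
  applied by centred convolution (no group delay). The recording is used
  as referenced at acquisition; no re-referencing.
* Relative power: frames of 1 s with 50% overlap, Hann taper, band power
  as the sum of squared rFFT magnitudes in [low, high); relative power
  divides by the four canonical bands' summed power per frame and per
  electrode (high-alpha 10–13 Hz is available as an extra band with the
  same denominator). Relative powers are computed per electrode first
  and then averaged over the electrode group (default: the eight midline
  channels); groups are configurable for regional analyses.

## Coupling estimation

Beta power and the HRV LF/HF series (15 s / 1 s sliding windows over the
full-record SPWVD — power is never re-estimated from 15 s segments) are
linearly resampled to a common 1 Hz grid over the intersection of their
supports. On each 15 s window both series are z-scored and:

* heart→brain: least squares of beta on na = 2 own lags plus nb = 2
  lags of HRV power at delay 2 samples; coefficient = Σ exogenous
  weights (invariant to delay ambiguity within the window).
* brain→heart: the window's standardized beta builds a deterministic
  synthetic cardiac predictor p(t) = (1 + 0.5·b̃(t))², the instantaneous
  band power of an oscillator whose amplitude is modulated by beta
  (floored at 0.05 to stay admissible); the observed HRV power is
  regressed on nb = 2 lags of the standardized predictor at delay 2.
  No random innovations enter the predictor, so the estimate is exactly
  reproducible.

The brain→heart regression carries **no autoregressive terms**
(na_b2h = 0). With them, the AR part of the heavily smoothed HRV power
series absorbs essentially all within-window variance and the exogenous
coefficient is unidentifiable — measured near zero and non-monotone in
the true coupling gain across a grid of lag structures and envelope
timescales. As a pure exogenous fit the coefficient is monotone in the
generator's gain and direction discrimination (congruent coefficient
family larger than the incongruent one under unidirectional driving)
holds. All orders are configurable in `CouplingConfig` and recorded in
output metadata. A limitation follows from the design: without AR
terms the brain→heart coefficient is correlational within the window,
and an ascending-coupled session produces a nonzero (smaller)
brain→heart reading too; condition *contrasts*, not absolute values,
carry the directional information — which is how the coefficients are
used.

Windows with constant or rank-deficient regressors are flagged and
withheld. Coefficient series are cubic-spline interpolated onto the EEG
frame grid (flagged windows excluded from the spline support, no
extrapolation); condition means may be taken on the interpolated series
(default) or the raw window series. The first 188 s of intervention
sessions are excluded before averaging. Participants whose averaged
HF2B falls outside their group's 5th–95th percentile range (linear
interpolation, strict exclusion outside the closed interval) are
dropped from coupling statistics only, with the exclusion logged; note
that for small groups this range criterion necessarily flags the group
extremes.

## Inference

* Wilcoxon signed rank, two-tailed: zero differences dropped, ties
  mid-ranked; exact p for n ≤ 25 from the rank-sum distribution built by
  dynamic programming over doubled (integer) ranks, normal approximation
  with tie-corrected variance above. Both W⁺ and W⁻ are reported since
  either orientation appears in common software.
* FDR: Benjamini–Hochberg within declared families — all-participant
  contrasts, per-group contrasts, coupling contrasts each form one
  family.
* Cliff's delta with the consistent-variance normal CI, truncated to
  [−1, 1].
* Response models: OLS of ΔSTAI = (before − after)/baseline on (i) LF,
  HF, LF/HF; (ii) midline alpha, beta; (iii) the four coupling
  coefficients, using intervention-condition means. Cohen's d per
  predictor is 2t/√df_resid (recorded in metadata; other conventions
  exist and none is canonical), with the usual large-sample d variance
  for its CI. Condition numbers above 1e8 log a collinearity warning.
* Split-half reliability: per participant, windowed values split by
  odd/even index; cohort Spearman correlation of odd vs even means,
  stepped up by Spearman–Brown 2r/(1+r).
* Sample size: smallest n such that the two-sided paired t test with
  noncentrality d√n and df n−1 reaches the requested power, by scanning
  the noncentral-t power expression (d = 0.6, α = 0.05, power = 0.8
  gives n = 24).

## Problem sizes and determinism

Validation runs use scaled-down sessions — 300–600 s, ECG at 250 Hz,
EEG at 128 Hz on the eight midline channels, cohorts of 8 + 6 — which
preserve every structural constant of the full protocol (188 s paced
epoch, band edges, window/step settings, exclusion rule). Full-scale
defaults (1200 s, 1 kHz, 20 min sessions) remain the configuration
defaults. The end-to-end cohort property (responders showing the
HF/LF-ratio/beta/B2H increases and H2B decreases, non-responders only
the LF rise) holds in 18 of 20 fixed seeds at this scale. All
randomness flows from `numpy.random.default_rng` seeds carried in the
configs; identical config and seed reproduce outputs bit for bit, and
the run manifest records the config hash, package version, seeds and
per-participant processing log.

## I/O

EDF and BrainVision recordings are read through MNE. The package's own
interchange format is columnar CSV (time_s + one column per channel,
markers in a sidecar file, cohort STAI table as a flat CSV); CSV
round-trips are exact to the written precision (1e-6 µV).

## Known limitations

* The brain→heart coefficient is a windowed correlational estimate (see
  above); absolute values are not causal strengths.
* The SPWVD clips residual negative cross terms to zero, biasing very
  low power estimates slightly upward.
* The 5–95% range criterion flags group extremes at small n; exclusions
  are logged so the effect is auditable.
* The IBI corrector assumes sinus rhythm with isolated artifacts;
  sustained arrhythmia violates its running-median premise (such
  recordings are the ones studies exclude).
* Split-half reliability assumes windowed values are exchangeable
  within participant; strong nonstationarity (e.g. the breathing epoch,
  if not excluded) inflates it.
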