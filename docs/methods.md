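# Methods

This note documents the generative model behind the synthetic data, the
signal-processing and statistical choices, and what the test suite does and
does not establish about real recordings.

## Study structure emulated

A randomized, placebo-controlled, three-period crossover: each subject
attends three sessions, one per dose condition (placebo, 720 mg "low",
1440 mg "high").  The first-session dose is randomized per subject; the
remaining two follow a fixed rotation (high → placebo → low;
low → high → placebo; placebo → low → high), so every subject receives
every condition exactly once.  Within a session, measurements are taken at
a pretreatment baseline and hourly post-dose: EEG is analyzed over hours
1–4, plasma metabolites over hours 1–5.  A session's EEG consists of
alternating 1-minute eyes-closed/eyes-open resting segments (two of each)
followed by three ASSR blocks (40, 30, 20 Hz click trains; 110 standard
trials per block; 500 ms trains of 1 ms clicks; 3 s inter-trial interval;
11 oddball trains per session, randomly spread over blocks, excluded from
analysis).

## Generative EEG model

No ground-truth generative model of the recorded EEG exists, so the
simulator is deliberately built from components whose downstream measures
have closed-form or Monte-Carlo oracles:

* **Background**: per-channel `1/f^χ` colored noise (spectral synthesis:
  white Gaussian noise shaped by `f^{−χ/2}`, unit variance), default
  χ = 1, RMS 10 µV.  The slope estimator must recover χ; this is tested
  for χ ∈ {0, 0.5, 1, 1.5}.
* **Alpha rhythm**: 10 Hz sinusoid with posterior topography, amplitude
  5 µV, doubled with eyes closed.  It exists so the slope fit's exclusion
  band (6–14 Hz) has something to exclude.
* **Steady-state response**: during each click-train trial a sinusoid at
  the train's repetition rate is added to fronto-central channels for the
  train duration.  Its per-trial phase is von Mises(0, κ) and its amplitude
  and κ depend on dose.  Trial phases are drawn from a spawned child RNG
  stream so that the main stream's consumption is identical across dose
  conditions: simulations of two doses at the same seed share their
  background-noise realization, which makes paired dose comparisons sharp
  and is what the monotonicity tests exploit.
* **Resting gamma**: band-limited (30–50 Hz) Gaussian noise added during
  resting segments, amplitude dose-dependent — the substrate of the
  resting-gamma dose effect.
* **Artifacts**: blink transients (350 ms Hann pulses, 200 µV, frontal
  topography, Poisson arrivals at 3/min) so peak-to-peak rejection has
  work to do, and a 2 µV 60 Hz mains component motivating the 58–62 Hz
  band exclusion.

Montage: 8 channels (Fz, FCz, Cz, CPz, Pz, F3, F4, Oz) at 500 Hz — enough
to give the ASSR ROI (Fz, FCz, Cz), a posterior alpha focus and frontal
blink sites, at desk scale.  Pre-dose baseline recordings are always
generated at drug-free effect levels regardless of the session's assigned
dose.

### Dose-effect calibration

The dose effect on the ASSR is carried by the entrainment amplitude
(placebo 1.05, low 1.15, high 1.6 µV) with the per-dose phase
concentration (κ = 10, 6, 2.05) set so that the condition-mean 40 Hz ITPC
lands near 0.18 under placebo and near 0.20 under the high dose at the
full 110-trial block scale — the anchors the simulator is calibrated to.
The resulting evoked-power separation (relative change ≈ 0.02 placebo vs
≈ 0.08 high) makes the high dose, but not the low dose, statistically
separable at study scale, reproducing the qualitative target-engagement
pattern.  Two simplifications are worth noting: the same entrainment
effect applies at all three stimulation rates (in humans the effect is
gamma-band specific), and the effect is constant over post-dose hours (no
pharmacodynamic time course).

### What the simulator does not emulate

Real volume conduction and channel covariance, non-stationary artifacts
(movement, sweat, electrode drift), oscillatory bursts, evoked onset
responses, and individual alpha-frequency variation.  Passing tests
therefore establish the correctness of the estimators and the statistical
machinery under a known generative model — not preprocessing robustness on
arbitrary clinical EEG.

## Pharmacokinetics

Metabolite trajectories follow a one-compartment oral model (Bateman
function) plus, for endogenous analytes, a baseline with a 24 h cosine
diurnal term.  Defaults ka = 2.0/h and ke = ln2/1.75/h give
tmax = ln(ka/ke)/(ka−ke) ≈ 1.01 h and half-life 1.75 h, inside the 1–2 h
and 1.5–2 h windows reported for this compound class.  Measurement noise is
multiplicative log-normal (CV 10%).  Drug-derived analytes (4-Cl-KYN,
7-Cl-KYNA, 4-Cl-3-HAA) have zero endogenous baseline and dose-proportional
scale; KYN and QUIN are simulated with no dose response, matching the
pattern the statistics stage should find.

## Signal processing

* **Filtering**: order-4 Butterworth band-pass 1–80 Hz applied
  forward-backward (zero phase; squared magnitude response, <1% amplitude
  error at 40 Hz, >99.99% rejection of 0.1 Hz drift), then average
  reference.
* **Epoching**: index-exact windows [−0.5, 1.0] s around train onsets;
  out-of-bounds trials are flagged, never silently dropped; oddballs
  excluded.
* **Rejection**: peak-to-peak > 150 µV on any channel.  No ICA or ocular
  regression — rejection keeps the stage deterministic.
* **Morlet transform**: n_cycles = 7, Gaussian envelope truncated at
  ± n_cycles/(2f), amplitude-normalized so a sinusoid of amplitude a has
  |coefficient| = a (hence |coeff|² is µV²); verified against an explicit
  complex-demodulation oracle to machine precision.  Wavelets must fit the
  epoch (n_cycles/f ≤ epoch length), which bounds the analyzable grid at
  ≈5 Hz for the default window; displayed power maps start where half a
  wavelet also fits the baseline window (≈12 Hz).
* **ASSR scoring**: mean over ROI × (rate ± 2 Hz) × 0.1–0.5 s of either
  ITPC or baseline-corrected power (baseline −0.4 to −0.1 s; relative
  change by default, dB optional).  Whether the reported power should
  additionally be corrected against the pretreatment session is left as a
  config choice (`power_mode`, plus the baseline covariate in the model);
  the default is within-epoch correction only, with the session baseline
  handled by the statistics stage.
* **Welch PSD**: 2 s Hamming windows, 50% overlap, averaged within
  eyes-closed and eyes-open segment sets, then the two set means averaged
  with equal weight.
* **Resting gamma**: trapezoidal band integral 30–50 Hz (58–62 Hz
  excluded), ROI mean, in dB.
* **1/f slope**: plain OLS of log-power on log-frequency over 3–40 Hz
  excluding 6–14 Hz; no peak-parameterization model, by design — the
  estimator is transparent, and its bias under the simulator's alpha peak
  is shown to be negligible once the peak band is excluded.

## Statistics

The per-measure model is the trial's: dose (3 levels, placebo reference)
as fixed effect, random intercept per subject, time and pretreatment
baseline as covariates; EEG hours 1–4, other measures 1–5.  Implementation
choices that were genuinely open:

* **Estimation** is REML profiled to the single variance ratio
  θ = τ²/σ²: at each θ the fixed effects solve in closed form (per-group
  inverse `(I + θJ)⁻¹ = I − θ/(1+θn_g) J`), so fitting is a bounded scalar
  minimization over log θ ∈ [−12, 12] (xatol 1e-10) with an explicit θ = 0
  boundary comparison.  This cannot diverge, and a cross-check test shows
  it reproduces a general-purpose mixed-model fitter's fixed effects and
  variance components to ~1e-5 on well-conditioned problems.  The
  fixed-effect covariance is the model-based GLS covariance
  `σ̂²(X'V⁻¹X)⁻¹`.
* **Time** enters categorically by default (linear optional): four hourly
  levels carry no strong ordering assumption worth imposing.
* **Baseline covariate coding**: the session baseline is a noisy
  re-measurement of exactly the subject trait the random intercept models.
  Entered raw, the covariate is endogenous (correlated with the random
  effect), and null simulation at study conditions shows the omnibus dose
  test inflating to ~6.5–7%.  Centering the baseline within subject — its
  between-subject component is the random intercept's job — restores the
  empirical size to ~4–5%.  Within-subject centering is therefore the
  default (`baseline_centering="within"`), with `"raw"` available.  A
  baseline with zero variance (drug-derived analytes are absent pre-dose)
  is dropped from the model with a log message.
* **Degrees of freedom**: between-within (response rows − subjects −
  within-subject fixed-effect parameters), recorded in the output
  metadata; at the default scale (120 rows, 10 subjects) the denominator
  df is ~104, so t vs z matters little.  The omnibus dose test is the Wald
  statistic on the two dose coefficients scaled to F(2, df).
* **Multiplicity**: measures are tested separately without correction, as
  in the trial report; a Benjamini–Hochberg option exists but is off by
  default.

Operating characteristics under the measurement-level null simulator
(grand mean 0.18, subject SD 0.03, residual SD 0.02 — the 40 Hz ITPC
scale): empirical type-I error 4–5% across 500-replicate runs; power for
the default high-dose-only effect of +0.02 is ≈99% at 10 subjects.

## Problem sizes

Full study scale is 10 subjects × 3 sessions × (baseline + 4 h) × 3 blocks
× 110 trials.  The bundled demo runs 4 subjects with 30-trial blocks and
15 s resting segments (end-to-end in about a minute); the study-scale runs
used by the acceptance machinery keep the trial's 10 subjects and all
timepoints but use 60-trial blocks and 15 s resting segments, which leaves
the dose contrasts well powered while keeping a full simulate→analyze
cycle in the minutes range.  ITPC calibration anchors are always measured
at the full 110-trial block scale, where the Rayleigh null floor (≈0.085)
is well below the anchor values.

## I/O formats

Recordings are written as plain EDF (16-bit, 1 s records, physical units
µV, per-channel symmetric ranges) with events in a tab-separated sidecar
(`*_events.tsv`: 0-based `onset_sample`, `duration` in samples, `code`);
reading goes through MNE's EDF parser, so the round-trip test exercises an
independent implementation.  Feature tables and metabolite series are
UTF-8 CSV with header, period decimals; model results are JSON plus a
report-shaped CSV.  All indices are 0-based with half-open intervals.

## Known limitations

The simulator's channel covariance is white across channels (no leadfield
mixing), its dose effects are time-constant, and the resting-gamma dB
scale is arbitrary (set by the generator's amplitudes, not matched to any
amplifier's units).  The between-within df approximation is coarser than
Satterthwaite for badly unbalanced designs; the design here is balanced by
construction, and missing-dose subjects only raise a warning.  EDF writing
requires integer sampling rates and whole-second recordings.
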