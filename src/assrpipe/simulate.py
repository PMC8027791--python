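"""Synthetic EEG generator emulating the crossover ASSR/resting study.

No generative model of the recorded EEG exists to copy, so the simulator is
built from components whose downstream measures have closed-form or
Monte-Carlo oracles:

* 1/f^chi colored background noise (power-law spectrum, the aperiodic
  component the slope estimator must recover);
* a posterior alpha rhythm, stronger with eyes closed;
* during every click-train trial, a sinusoid at the train's repetition rate
  on fronto-central channels whose per-trial phase is von Mises(0, kappa) —
  kappa and amplitude carry the dose effect on phase locking (ITPC) and
  evoked power;
* band-limited 30-50 Hz activity in resting segments whose amplitude
  carries the dose effect on resting gamma power;
* blink transients on frontal channels (Poisson arrivals) and a 60 Hz mains
  component, so artifact rejection and band exclusions have something to do.

A session recording is: alternating 1-min eyes-closed / eyes-open resting
segments (two of each), then one stimulation block per repetition rate
(40, 30, 20 Hz).  The pretreatment-baseline timepoint is always generated
at no-drug (placebo) effect levels, whatever the session's dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .design import BASELINE, DOSES, PLACEBO, SessionDesign
from .io_formats import EEGRecording
from .stimulus import ClickTrainSpec, make_session_sequence

#: simulated montage: fronto-central ASSR generators, posterior alpha, frontal
#: blink-sensitive sites
CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz", "F3", "F4", "Oz")

DEFAULT_FS = 500.0

# per-channel spatial gains of each signal component
_ASSR_GAIN = {"Fz": 1.0, "FCz": 1.0, "Cz": 0.8, "CPz": 0.5, "Pz": 0.2,
              "F3": 0.4, "F4": 0.4, "Oz": 0.1}
_ALPHA_GAIN = {"Fz": 0.1, "FCz": 0.1, "Cz": 0.3, "CPz": 0.6, "Pz": 1.0,
               "F3": 0.1, "F4": 0.1, "Oz": 1.0}
_BLINK_GAIN = {"Fz": 1.0, "FCz": 0.5, "Cz": 0.2, "CPz": 0.1, "Pz": 0.0,
               "F3": 1.0, "F4": 1.0, "Oz": 0.0}


@dataclass(frozen=True)
class EffectConfig:
    """Amplitudes and dose effects of the generative EEG model.

    All amplitudes in µV.  Dose-keyed dicts must cover placebo/low/high;
    kappa is the von Mises concentration of per-trial steady-state phases
    (kappa=0: uniform phases, no locking; kappa→inf: perfect locking).
    """

    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0  # RMS of the broadband background
    ssr_amplitude: dict = field(
        default_factory=lambda: {"placebo": 1.05, "low": 1.15, "high": 1.6}
    )
    phase_concentration: dict = field(
        default_factory=lambda: {"placebo": 10.0, "low": 6.0, "high": 2.05}
    )
    resting_gamma_amplitude: dict = field(
        default_factory=lambda: {"placebo": 1.0, "low": 1.0, "high": 1.25}
    )
    alpha_amplitude: float = 5.0
    blink_rate: float = 3.0  # events per minute
    blink_amplitude: float = 200.0
    line_noise_amplitude: float = 2.0
    line_freq: float = 60.0
    eyes_open_noise_factor: float = 1.2
    seed: int | None = None  # recorded in output metadata by the pipeline

    def __post_init__(self) -> None:
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        for name in ("ssr_amplitude", "phase_concentration",
                     "resting_gamma_amplitude"):
            table = getattr(self, name)
            missing = [d for d in DOSES if d not in table]
            if missing:
                raise ValueError(f"{name} missing dose conditions {missing}")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} values must be >= 0")
        for name in ("noise_amplitude", "alpha_amplitude", "blink_rate",
                     "blink_amplitude", "line_noise_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def colored_noise(
    n_samples: int, fs: float, chi: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-variance noise with power spectral density ∝ f^(-chi).

    Spectral-synthesis method: white Gaussian noise is shaped in the
    frequency domain by f^(-chi/2) (DC removed), then normalized.
    """
    if chi < 0:
        raise ValueError("chi must be >= 0")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    white = rng.standard_normal(n_samples)
    if chi == 0:
        x = white
    else:
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-chi / 2.0)
        x = np.fft.irfft(spectrum * shape, n=n_samples)
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def _band_limited_noise(
    n_samples: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to a frequency band."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _blink_waveform(fs: float, duration: float = 0.35) -> np.ndarray:
    n = max(3, int(round(duration * fs)))
    return np.hanning(n)


def default_block_specs(
    trials_per_block: int = 110,
    n_oddball: int = 11,
    iti: float = 3.0,
    rates: tuple[float, ...] = (40.0, 30.0, 20.0),
) -> list[ClickTrainSpec]:
    """The session's stimulation blocks, one spec per repetition rate."""
    return [
        ClickTrainSpec(rep_rate=r, n_standard=trials_per_block,
                       n_oddball=n_oddball, iti=iti)
        for r in rates
    ]


def simulate_recording(
    design: SessionDesign,
    timepoint: str,
    effect: EffectConfig,
    specs: list[ClickTrainSpec] | None = None,
    fs: float = DEFAULT_FS,
    rng: np.random.Generator | None = None,
    resting_segment_s: float = 60.0,
    n_resting_pairs: int = 2,
    include_resting: bool = True,
    include_assr: bool = True,
) -> EEGRecording:
    """Simulate one continuous recording for a subject-session-timepoint.

    The recording contains (in order) ``n_resting_pairs`` eyes-closed /
    eyes-open resting pairs, then one ASSR block per spec.  Event markers
    are embedded for every resting segment and every trial onset with codes
    like ``rest/ec``, ``rest/eo``, ``assr40/standard``, ``assr40/oddball``.
    """
    if rng is None:
        rng = np.random.default_rng(effect.seed)
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz to resolve the gamma band")
    if design.dose not in DOSES:
        raise ValueError(f"unknown dose condition {design.dose!r}")
    if specs is None:
        specs = default_block_specs()
    # pre-dose baseline is drug-free whatever the session's assignment
    dose = PLACEBO if timepoint == BASELINE else design.dose

    segments = []  # (kind, n_samples) with kind in {ec, eo, block index}
    if include_resting:
        for _ in range(n_resting_pairs):
            segments.append(("rest/ec", int(round(resting_segment_s * fs))))
            segments.append(("rest/eo", int(round(resting_segment_s * fs))))
    block_trials: dict[int, pd.DataFrame] = {}
    if include_assr:
        session_seq = make_session_sequence(specs, rng, t_start=0.0, gap=0.0)
        for i, spec in enumerate(specs):
            trials = session_seq[session_seq["rep_rate"] == spec.rep_rate]
            trials = trials.reset_index(drop=True)
            # re-time the block locally from zero
            local = trials["onset"] - trials["onset"].iloc[0]
            trials = trials.assign(onset=local)
            duration = local.iloc[-1] + spec.train_duration + 1.0
            segments.append((f"block{i}", int(np.ceil(duration) * fs)))
            block_trials[i] = trials

    n_total = sum(n for _, n in segments)
    n_ch = len(CHANNELS)
    data = np.zeros((n_ch, n_total))
    events = []

    line_phase = rng.uniform(0, 2 * np.pi)
    t_all = np.arange(n_total) / fs
    if effect.line_noise_amplitude > 0:
        line = effect.line_noise_amplitude * np.sin(
            2 * np.pi * effect.line_freq * t_all + line_phase
        )
        data += line[None, :]

    cursor = 0
    for seg_idx, (kind, n_seg) in enumerate(segments):
        t_seg = np.arange(n_seg) / fs
        resting = kind.startswith("rest")
        eyes_closed = kind == "rest/ec"
        noise_scale = effect.noise_amplitude * (
            effect.eyes_open_noise_factor if kind == "rest/eo" else 1.0
        )
        seg = np.empty((n_ch, n_seg))
        for c in range(n_ch):
            seg[c] = noise_scale * colored_noise(
                n_seg, fs, effect.noise_exponent, rng
            )
        # posterior alpha, stronger with eyes closed
        alpha_amp = effect.alpha_amplitude * (2.0 if eyes_closed else 0.8)
        alpha = alpha_amp * np.sin(2 * np.pi * 10.0 * t_seg + rng.uniform(0, 2 * np.pi))
        for c, ch in enumerate(CHANNELS):
            seg[c] += _ALPHA_GAIN[ch] * alpha

        if resting:
            gamma_amp = effect.resting_gamma_amplitude[dose]
            if gamma_amp > 0:
                for c in range(n_ch):
                    seg[c] += gamma_amp * _band_limited_noise(
                        n_seg, fs, (30.0, 50.0), rng
                    )
            events.append((cursor, n_seg, kind))
        else:
            block_idx = int(kind.removeprefix("block"))
            spec = specs[block_idx]
            trials = block_trials[block_idx]
            amp = effect.ssr_amplitude[dose]
            kappa = effect.phase_concentration[dose]
            n_train = int(round(spec.train_duration * fs))
            t_train = np.arange(n_train) / fs
            # phases come from a spawned child stream so that the main
            # stream's consumption (noise, blinks) is identical across dose
            # conditions — dose comparisons at equal seeds share their
            # background noise realization
            phase_rng = np.random.default_rng(int(rng.integers(2**63)))
            if kappa > 0:
                phases = phase_rng.vonmises(0.0, kappa, size=len(trials))
            else:
                phases = phase_rng.uniform(-np.pi, np.pi, size=len(trials))
            for ti_, (_, trial) in enumerate(trials.iterrows()):
                onset_sample = int(round(trial["onset"] * fs))
                phase = phases[ti_]
                burst = amp * np.sin(2 * np.pi * spec.rep_rate * t_train + phase)
                sl = slice(onset_sample, onset_sample + n_train)
                for c, ch in enumerate(CHANNELS):
                    seg[c, sl] += _ASSR_GAIN[ch] * burst
                code = f"assr{int(spec.rep_rate)}/{trial['condition']}"
                events.append((cursor + onset_sample, n_train, code))

        data[:, cursor : cursor + n_seg] = seg
        cursor += n_seg

    # blinks: Poisson arrivals over the whole recording, frontal topography
    if effect.blink_rate > 0 and effect.blink_amplitude > 0:
        wave = _blink_waveform(fs)
        expected = effect.blink_rate * (n_total / fs) / 60.0
        n_blinks = rng.poisson(expected)
        starts = np.sort(rng.integers(0, max(1, n_total - len(wave)), size=n_blinks))
        for s in starts:
            sl = slice(s, s + len(wave))
            for c, ch in enumerate(CHANNELS):
                data[c, sl] += _BLINK_GAIN[ch] * effect.blink_amplitude * wave

    events_df = pd.DataFrame(events, columns=["onset_sample", "duration", "code"])
    return EEGRecording(
        fs=fs,
        channel_labels=list(CHANNELS),
        data=data,
        events=events_df,
        meta={
            "subject_id": design.subject_id,
            "visit": design.visit,
            "dose": design.dose,
            "timepoint": timepoint,
        },
    )


def simulate_assr_block(
    dose: str,
    effect: EffectConfig,
    spec: ClickTrainSpec,
    fs: float = DEFAULT_FS,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Simulate a single stimulation block (no resting segments).

    Convenience wrapper used for calibration anchors and oracle tests; the
    block is generated at the given dose's post-dose effect levels.
    """
    design = SessionDesign(subject_id="S00", visit=1, dose=dose)
    return simulate_recording(
        design,
        timepoint="h1",
        effect=effect,
        specs=[spec],
        fs=fs,
        rng=rng,
        include_resting=False,
    )


def simulate_feature_table(
    n_subjects: int,
    rng: np.random.Generator,
    measure: str = "assr40_itpc",
    dose_effects: dict | None = None,
    grand_mean: float = 0.18,
    sd_subject: float = 0.03,
    sd_resid: float = 0.02,
    timepoints: tuple[str, ...] = ("h1", "h2", "h3", "h4"),
    time_effects: dict | None = None,
) -> pd.DataFrame:
    """Simulate a long-format measurement table directly (no EEG).

    Generative model of one measure in the crossover:

        y[subject, dose, time] = grand_mean + b_subject + effect[dose]
                                 + time_effect[time] + e

    with b ~ N(0, sd_subject²) shared across the subject's three sessions
    and e ~ N(0, sd_resid²) per measurement.  The pretreatment baseline is
    an independent drug-free measurement of the same measure.  Defaults
    place the measure on the 40 Hz ITPC scale with a high-dose-only effect.
    Used for the statistics stage's type-I-error and power simulations.
    """
    if dose_effects is None:
        dose_effects = {PLACEBO: 0.0, "low": 0.0, "high": 0.02}
    if time_effects is None:
        time_effects = {tp: 0.0 for tp in timepoints}
    rows = []
    for i in range(n_subjects):
        subject = f"S{i + 1:02d}"
        b = rng.normal(0.0, sd_subject)
        for dose in DOSES:
            baseline = grand_mean + b + rng.normal(0.0, sd_resid)
            rows.append(
                dict(subject_id=subject, dose=dose, timepoint=BASELINE,
                     measure=measure, value=baseline, baseline_value=np.nan)
            )
            for tp in timepoints:
                y = (grand_mean + b + dose_effects[dose]
                     + time_effects[tp] + rng.normal(0.0, sd_resid))
                rows.append(
                    dict(subject_id=subject, dose=dose, timepoint=tp,
                         measure=measure, value=y, baseline_value=baseline)
                )
    return pd.DataFrame(rows)
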