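"""Spectral outcome measures: ASSR evoked power and phase coherence,
resting gamma power, and the aperiodic 1/f slope.

Four measures per session-timepoint:

* **ASSR evoked power** — Morlet time-frequency power, trial-averaged and
  corrected against the pre-stimulus baseline, averaged over a
  fronto-central ROI, the stimulation rate ±2 Hz, and the steady-state
  window 0.1–0.5 s after train onset.
* **ITPC** — inter-trial phase coherence, the magnitude of the mean unit
  phase vector across trials at each channel/frequency/time, averaged over
  the same ROI/band/window.  1 = perfect phase locking; for N uniformly
  random phases the expected value is the Rayleigh resultant
  sqrt(pi)/(2 sqrt(N)), not zero.
* **Resting gamma power** — 10·log10 of Welch band power (30–50 Hz, mains
  band excluded) averaged over the ROI.
* **1/f slope** — OLS slope of log10 power vs log10 frequency over
  3–40 Hz with the theta/alpha peak region excluded; the regression
  coefficient equals minus the power-law exponent chi.

The Morlet transform is amplitude-normalized: a pure sinusoid of amplitude
a yields |coefficient| = a at its frequency, so |coeff|² is µV².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .preprocessing import Epochs

logger = logging.getLogger(__name__)

#: fronto-central ROI where the ASSR is maximal in the simulated montage
DEFAULT_ROI = ("Fz", "FCz", "Cz")
DEFAULT_GAMMA_BAND = (30.0, 50.0)
DEFAULT_LINE_EXCLUSION = (58.0, 62.0)
DEFAULT_SLOPE_RANGE = (3.0, 40.0)
DEFAULT_SLOPE_EXCLUSIONS = ((6.0, 14.0),)


@dataclass
class TFR:
    """Complex Morlet coefficients of retained trials.

    coefficients : (n_trials, n_channels, n_freqs, n_times), complex
    trial_indices : indices of these trials in the source Epochs
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: float
    fs: float
    condition: str
    channel_labels: list[str]
    trial_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def channel_index(self, labels) -> np.ndarray:
        return np.array([self.channel_labels.index(l) for l in labels], dtype=int)


@dataclass
class PSD:
    """Averaged power spectral density per channel (µV²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channel_labels: list[str]
    window_s: float
    overlap: float
    taper: str = "hamming"
    n_segments: int = 0

    def channel_index(self, labels) -> np.ndarray:
        return np.array([self.channel_labels.index(l) for l in labels], dtype=int)


@dataclass(frozen=True)
class AssrScore:
    """Scalar ASSR outcome for one condition (power or ITPC)."""

    condition: str
    measure: str  # "power" | "itpc"
    value: float
    roi: tuple[str, ...]
    band: tuple[float, float]
    window: tuple[float, float]
    n_trials: int


@dataclass(frozen=True)
class RestingScore:
    """Scalar resting-state outcomes: gamma power (dB) and 1/f slope."""

    gamma_db: float
    slope: float
    slope_stderr: float
    fit_range: tuple[float, float]
    excluded_bands: tuple[tuple[float, float], ...]


def _morlet_kernel(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Amplitude-normalized complex Morlet kernel at one frequency.

    Gaussian envelope with sigma_t = n_cycles/(2 pi f), truncated at
    ±n_cycles/(2f) (≈ ±pi sigma); normalized so convolution with
    a·cos(2 pi f t + phi) yields a·exp(i(2 pi f t + phi)).
    """
    n_half = int(round(n_cycles / (2.0 * freq) * fs))
    t = np.arange(-n_half, n_half + 1) / fs  # symmetric, odd length
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(1j * 2.0 * np.pi * freq * t)
    return 2.0 * kernel / envelope.sum()


def morlet_tfr(
    epochs: Epochs,
    freqs: np.ndarray,
    n_cycles: float = 7.0,
) -> TFR:
    """Morlet wavelet transform of the retained trials of an Epochs object.

    Preconditions: every wavelet must fit in the epoch
    (n_cycles / f <= epoch duration) and freqs must stay below Nyquist.
    Coefficients near the epoch edges contain wrap-in from zero padding;
    scoring windows should stay >= half a wavelet from the edges.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    duration = epochs.data.shape[2] / epochs.fs
    for f in freqs:
        if n_cycles / f > duration:
            raise ValueError(
                f"wavelet at {f:g} Hz ({n_cycles / f:.2f} s at {n_cycles} "
                f"cycles) does not fit in the {duration:.2f} s epoch"
            )
        if f >= epochs.fs / 2:
            raise ValueError(f"frequency {f:g} Hz at or above Nyquist")
    data = epochs.retained_data()
    n_trials, n_ch, n_samp = data.shape
    coeffs = np.empty((n_trials, n_ch, len(freqs), n_samp), dtype=complex)
    for fi, f in enumerate(freqs):
        kernel = _morlet_kernel(f, n_cycles, epochs.fs)
        # same-mode FFT convolution along time for all trials/channels at once
        coeffs[:, :, fi, :] = sp_signal.fftconvolve(
            data, kernel[None, None, :], mode="same", axes=2
        )
    return TFR(
        coefficients=coeffs,
        freqs=freqs,
        times=epochs.times,
        n_cycles=n_cycles,
        fs=epochs.fs,
        condition=epochs.condition,
        channel_labels=list(epochs.channel_labels),
        trial_indices=epochs.retained,
    )


def itpc(tfr: TFR) -> np.ndarray:
    """Inter-trial phase coherence over (channels, freqs, times).

    ITPC(c,f,t) = | mean_n coeff_n/|coeff_n| | over retained trials.
    Zero-magnitude coefficients (no phase defined) are excluded at that
    point and logged.
    """
    if tfr.coefficients.shape[0] < 2:
        raise ValueError("ITPC requires at least 2 retained trials")
    mag = np.abs(tfr.coefficients)
    valid = mag > 0
    n_invalid = int(valid.size - valid.sum())
    if n_invalid:
        logger.info("ITPC: excluded %d zero-magnitude coefficients", n_invalid)
    unit = np.where(valid, tfr.coefficients / np.where(valid, mag, 1.0), 0.0)
    n_valid = valid.sum(axis=0)
    resultant = np.abs(unit.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_valid > 0, resultant / np.maximum(n_valid, 1), np.nan)
    return out


def evoked_power(
    tfr: TFR,
    baseline_window: tuple[float, float] = (-0.4, -0.1),
    mode: str = "relchange",
) -> np.ndarray:
    """Trial-averaged power corrected against the pre-stimulus baseline.

    Per channel and frequency, the mean power over the baseline window B is
    subtracted: ``relchange`` = (P - B)/B; ``db`` = 10 log10(P/B).
    Returns (channels, freqs, times).
    """
    b0, b1 = baseline_window
    if not (b0 < b1 <= 0):
        raise ValueError("baseline window must precede the trial onset")
    if tfr.times[0] > b0:
        raise ValueError("baseline window lies outside the epoch")
    # baseline must hold at least one wavelet of the slowest frequency
    if (b1 - b0) < tfr.n_cycles / tfr.freqs[0] / 2:
        raise ValueError(
            "baseline window shorter than half a wavelet at "
            f"{tfr.freqs[0]:g} Hz"
        )
    power = np.mean(np.abs(tfr.coefficients) ** 2, axis=0)  # (ch, f, t)
    bmask = (tfr.times >= b0) & (tfr.times <= b1)
    baseline = power[:, :, bmask].mean(axis=2, keepdims=True)
    if np.any(baseline <= 0):
        raise ValueError("non-positive baseline power")
    if mode == "relchange":
        return power / baseline - 1.0
    if mode == "db":
        return 10.0 * np.log10(power / baseline)
    raise ValueError(f"unknown mode {mode!r}")


def assr_score(
    tfr: TFR,
    measure: str,
    roi: tuple[str, ...] = DEFAULT_ROI,
    band: tuple[float, float] | None = None,
    window: tuple[float, float] = (0.1, 0.5),
    baseline_window: tuple[float, float] = (-0.4, -0.1),
    power_mode: str = "relchange",
) -> AssrScore:
    """Collapse a TFR to one scalar ASSR outcome.

    The scalar is the mean over ROI channels, the stimulation rate ±2 Hz
    (default band), and the steady-state window of either the
    baseline-corrected power or the ITPC.  An empty retained-trial set
    yields a NaN score with a logged reason, never a silent zero.
    """
    if len(roi) == 0:
        raise ValueError("roi must be non-empty")
    rep_rate = float(tfr.condition.removeprefix("assr"))
    if band is None:
        band = (rep_rate - 2.0, rep_rate + 2.0)
    n_trials = tfr.coefficients.shape[0]
    if n_trials == 0:
        logger.warning("%s/%s: no retained trials, score is missing",
                       tfr.condition, measure)
        return AssrScore(tfr.condition, measure, float("nan"), tuple(roi),
                         band, window, 0)
    if measure == "power":
        values = evoked_power(tfr, baseline_window, mode=power_mode)
    elif measure == "itpc":
        values = itpc(tfr)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    ch = tfr.channel_index(roi)
    fmask = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tmask = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not fmask.any():
        raise ValueError(f"band {band} outside the frequency grid")
    scalar = float(values[np.ix_(ch, np.where(fmask)[0], np.where(tmask)[0])].mean())
    return AssrScore(tfr.condition, measure, scalar, tuple(roi), band,
                     window, n_trials)


def welch_psd(
    segments: list[np.ndarray],
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    channel_labels: list[str] | None = None,
) -> PSD:
    """Welch power spectral density averaged over segments.

    Each segment is (channels x samples) and must be at least one window
    long; segments are averaged with equal weight (eyes-closed and
    eyes-open sets are typically combined upstream by averaging their two
    per-set PSDs).
    """
    if len(segments) == 0:
        raise ValueError("no usable resting segments")
    nperseg = int(round(window_s * fs))
    psds = []
    for seg in segments:
        seg = np.atleast_2d(seg)
        if seg.shape[1] < nperseg:
            raise ValueError(
                f"segment of {seg.shape[1] / fs:.2f} s shorter than the "
                f"{window_s:g} s Welch window"
            )
        f, p = sp_signal.welch(
            seg, fs=fs, window="hamming", nperseg=nperseg,
            noverlap=int(round(nperseg * overlap)), detrend="constant",
            scaling="density", axis=1,
        )
        psds.append(p)
    power = np.mean(psds, axis=0)
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(power.shape[0])]
    return PSD(freqs=f, power=power, channel_labels=list(channel_labels),
               window_s=window_s, overlap=overlap, n_segments=len(segments))


def combine_psds(psds: list[PSD]) -> PSD:
    """Average PSDs with equal weight (e.g. eyes-closed and eyes-open sets)."""
    if len(psds) == 0:
        raise ValueError("no PSDs to combine")
    base = psds[0]
    for p in psds[1:]:
        if not np.array_equal(p.freqs, base.freqs):
            raise ValueError("PSD frequency grids differ")
    power = np.mean([p.power for p in psds], axis=0)
    return PSD(freqs=base.freqs, power=power,
               channel_labels=base.channel_labels, window_s=base.window_s,
               overlap=base.overlap, n_segments=sum(p.n_segments for p in psds))


def band_power(
    psd: PSD,
    band: tuple[float, float],
    roi: tuple[str, ...] | None = None,
    exclude: tuple[float, float] | None = None,
) -> float:
    """Band-integrated power (µV², trapezoidal) averaged over ROI channels."""
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if exclude is not None:
        mask &= ~((psd.freqs >= exclude[0]) & (psd.freqs <= exclude[1]))
    if mask.sum() < 2:
        raise ValueError(f"band {band} covers fewer than 2 frequency bins")
    ch = psd.channel_index(roi) if roi is not None else np.arange(psd.power.shape[0])
    mean_power = psd.power[ch][:, mask].mean(axis=0)
    return float(np.trapezoid(mean_power, psd.freqs[mask]))


def gamma_power_db(
    psd: PSD,
    band: tuple[float, float] = DEFAULT_GAMMA_BAND,
    roi: tuple[str, ...] = DEFAULT_ROI,
    line_exclusion: tuple[float, float] = DEFAULT_LINE_EXCLUSION,
) -> float:
    """10·log10 of ROI-averaged band-integrated resting gamma power."""
    p = band_power(psd, band, roi=roi, exclude=line_exclusion)
    if p <= 0:
        raise ValueError("zero band power: cannot take log")
    return float(10.0 * np.log10(p))


def aperiodic_slope(
    psd: PSD,
    fit_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
    excluded_bands: tuple[tuple[float, float], ...] = DEFAULT_SLOPE_EXCLUSIONS,
    roi: tuple[str, ...] | None = None,
) -> tuple[float, float]:
    """OLS slope of log10(power) vs log10(frequency) — the 1/f exponent.

    Oscillatory peak regions (default: 6–14 Hz theta/alpha) are excluded
    from the fit; at least 10 frequency points must remain.  Returns
    (slope, standard error); for f^(-chi) input the slope estimates -chi.
    """
    mask = (psd.freqs >= fit_range[0]) & (psd.freqs <= fit_range[1])
    for lo, hi in excluded_bands:
        mask &= ~((psd.freqs >= lo) & (psd.freqs <= hi))
    mask &= psd.freqs > 0
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} frequency points in the fit range; "
            "need at least 10"
        )
    ch = psd.channel_index(roi) if roi is not None else np.arange(psd.power.shape[0])
    mean_power = psd.power[ch][:, mask].mean(axis=0)
    if np.any(mean_power <= 0):
        raise ValueError("non-positive power in fit range")
    fit = sp_stats.linregress(np.log10(psd.freqs[mask]), np.log10(mean_power))
    return float(fit.slope), float(fit.stderr)


def resting_scores(
    psd: PSD,
    gamma_band: tuple[float, float] = DEFAULT_GAMMA_BAND,
    roi: tuple[str, ...] = DEFAULT_ROI,
    line_exclusion: tuple[float, float] = DEFAULT_LINE_EXCLUSION,
    fit_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
    excluded_bands: tuple[tuple[float, float], ...] = DEFAULT_SLOPE_EXCLUSIONS,
) -> RestingScore:
    """Bundle the two resting-state outcomes from one PSD."""
    slope, stderr = aperiodic_slope(psd, fit_range, excluded_bands, roi=roi)
    return RestingScore(
        gamma_db=gamma_power_db(psd, gamma_band, roi, line_exclusion),
        slope=slope,
        slope_stderr=stderr,
        fit_range=fit_range,
        excluded_bands=tuple(excluded_bands),
    )
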