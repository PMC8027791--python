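"""Click-train stimulus design for the auditory steady-state response (ASSR).

The paradigm presents blocks of short click trains: each trial is a 500 ms
train of 1 ms clicks repeated at 20, 30 or 40 Hz, followed by a silent
inter-trial interval.  Standard trains use a 1000 Hz carrier; rare oddball
trains (2000 Hz carrier) keep the listener attending and are excluded from
analysis.  At EEG sampling rates the carrier tone is not resolvable, so a
click is rendered as a rectangular pulse and the carrier survives only as an
event label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: trial condition codes used in event tables
STANDARD = "standard"
ODDBALL = "oddball"


@dataclass(frozen=True)
class ClickTrainSpec:
    """Parameters of one ASSR stimulation condition.

    Parameters
    ----------
    rep_rate : float
        Click repetition rate in Hz (study conditions: 20, 30, 40).
    train_duration : float
        Duration of one click train in seconds.
    click_duration : float
        Duration of a single click in seconds.
    carrier : float
        Carrier tone frequency in Hz for standard trains (metadata).
    oddball_carrier : float
        Carrier tone frequency in Hz for oddball trains (metadata).
    n_standard : int
        Number of standard trials per block.
    n_oddball : int
        Number of oddball trials interleaved per session.
    iti : float
        Silent inter-trial interval in seconds (train offset to next onset).
    level_db : float
        Nominal sound level in dB; metadata only, never used in computation.
    """

    rep_rate: float = 40.0
    train_duration: float = 0.5
    click_duration: float = 0.001
    carrier: float = 1000.0
    oddball_carrier: float = 2000.0
    n_standard: int = 110
    n_oddball: int = 11
    iti: float = 3.0
    level_db: float = 80.0

    def __post_init__(self) -> None:
        n_clicks = self.rep_rate * self.train_duration
        if not np.isclose(n_clicks, round(n_clicks)):
            raise ValueError(
                f"rep_rate * train_duration = {n_clicks:g} is not a whole "
                "number of clicks"
            )
        if round(n_clicks) <= 0:
            raise ValueError("train must contain at least one click")
        if self.click_duration >= 1.0 / self.rep_rate:
            raise ValueError("click_duration must be shorter than the click period")
        if self.n_standard <= 0:
            raise ValueError("n_standard must be positive")
        if self.n_oddball < 0:
            raise ValueError("n_oddball must be non-negative")
        if self.iti <= 0:
            raise ValueError("iti must be positive")

    @property
    def n_clicks(self) -> int:
        """Number of clicks in one train."""
        return int(round(self.rep_rate * self.train_duration))

    @property
    def trial_spacing(self) -> float:
        """Onset-to-onset spacing in seconds (train + inter-trial interval)."""
        return self.train_duration + self.iti


def make_click_train(
    spec: ClickTrainSpec, fs: float, oddball: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Render one click train as a sampled waveform.

    Clicks are rectangular unit pulses of ``click_duration`` starting at
    onsets spaced ``1/rep_rate`` apart from t=0.  The oddball flag does not
    change the envelope (the carrier distinction is inaudible to the EEG
    model); it exists so callers can label events.

    Returns
    -------
    waveform : ndarray, shape (round(fs*train_duration),)
        0/1 envelope of the train.
    onsets : ndarray
        Click onset times in seconds.
    """
    if fs * spec.click_duration < 1.0:
        raise ValueError(
            f"fs={fs:g} Hz cannot render a {spec.click_duration * 1e3:g} ms click "
            "(less than one sample per click)"
        )
    n_samples = int(round(fs * spec.train_duration))
    onsets = np.arange(spec.n_clicks) / spec.rep_rate
    waveform = np.zeros(n_samples)
    click_samples = max(1, int(round(fs * spec.click_duration)))
    for onset in onsets:
        start = int(round(onset * fs))
        waveform[start : start + click_samples] = 1.0
    return waveform, onsets


def make_block_sequence(
    spec: ClickTrainSpec,
    rng: np.random.Generator,
    n_oddball: int | None = None,
    t_start: float = 0.0,
) -> pd.DataFrame:
    """Build the ordered trial list of one stimulation block.

    A block holds ``spec.n_standard`` standard trials with ``n_oddball``
    oddballs randomly interleaved among them.  Onset-to-onset spacing is
    ``train_duration + iti``.

    Parameters
    ----------
    n_oddball : int, optional
        Oddballs in this block.  Defaults to ``spec.n_oddball`` (i.e. a
        single-block session); session builders pass each block its share.

    Returns
    -------
    DataFrame with columns ``onset`` (s), ``rep_rate`` (Hz), ``condition``
    (``standard``/``oddball``), ``carrier`` (Hz).
    """
    if n_oddball is None:
        n_oddball = spec.n_oddball
    n_trials = spec.n_standard + n_oddball
    conditions = np.array([STANDARD] * spec.n_standard + [ODDBALL] * n_oddball)
    rng.shuffle(conditions)
    onsets = t_start + np.arange(n_trials) * spec.trial_spacing
    return pd.DataFrame(
        {
            "onset": onsets,
            "rep_rate": spec.rep_rate,
            "condition": conditions,
            "carrier": np.where(
                conditions == ODDBALL, spec.oddball_carrier, spec.carrier
            ),
        }
    )


def make_session_sequence(
    specs: list[ClickTrainSpec],
    rng: np.random.Generator,
    t_start: float = 0.0,
    gap: float = 5.0,
) -> pd.DataFrame:
    """Build the trial list of a full session (one block per repetition rate).

    The session's oddball budget (``n_oddball`` of the first spec) is
    distributed randomly over the blocks, so any individual block may carry
    0..n_oddball of them but the session total is exact.

    Parameters
    ----------
    specs : list of ClickTrainSpec
        One spec per block, in presentation order.
    gap : float
        Silent gap between blocks in seconds.
    """
    n_oddball_total = specs[0].n_oddball
    # multinomial split of the session oddball budget over blocks
    block_of_oddball = rng.integers(0, len(specs), size=n_oddball_total)
    per_block = np.bincount(block_of_oddball, minlength=len(specs))
    frames = []
    t = t_start
    for spec, n_odd in zip(specs, per_block):
        block = make_block_sequence(spec, rng, n_oddball=int(n_odd), t_start=t)
        frames.append(block)
        t = block["onset"].iloc[-1] + spec.trial_spacing + gap
    out = pd.concat(frames, ignore_index=True)
    out.index.name = "trial"
    return out
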