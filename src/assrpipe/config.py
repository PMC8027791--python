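"""Pipeline configuration: one serializable object drives a full run."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import EEG_TIMEPOINTS, METABOLITE_TIMEPOINTS
from .simulate import DEFAULT_FS, EffectConfig


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a simulate→analyze→report run.

    A run is a pure function of (config, seed): identical inputs give
    bit-identical datasets, feature tables, and reports.
    """

    seed: int = 0
    n_subjects: int = 10
    fs: float = DEFAULT_FS
    # stimulus
    trials_per_block: int = 110
    n_oddball: int = 11
    iti: float = 3.0
    rates: tuple[float, ...] = (40.0, 30.0, 20.0)
    # resting design
    resting_segment_s: float = 60.0
    n_resting_pairs: int = 2
    # session timepoints
    eeg_timepoints: tuple[str, ...] = EEG_TIMEPOINTS
    metabolite_timepoints: tuple[str, ...] = METABOLITE_TIMEPOINTS
    # generative EEG model
    effect: EffectConfig = field(default_factory=EffectConfig)
    # preprocessing
    band: tuple[float, float] = (1.0, 80.0)
    epoch_window: tuple[float, float] = (-0.5, 1.0)
    reject_uv: float = 150.0
    # features
    n_cycles: float = 7.0
    assr_window: tuple[float, float] = (0.1, 0.5)
    assr_halfband: float = 2.0
    baseline_window: tuple[float, float] = (-0.4, -0.1)
    power_mode: str = "relchange"
    welch_window_s: float = 2.0
    roi: tuple[str, ...] = ("Fz", "FCz", "Cz")
    # statistics
    time_as_categorical: bool = True
    baseline_centering: str = "within"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "effect" in d and isinstance(d["effect"], dict):
            d["effect"] = EffectConfig(**d["effect"])
        for key in ("rates", "eeg_timepoints", "metabolite_timepoints",
                    "band", "epoch_window", "assr_window",
                    "baseline_window", "roi"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def study_scale_config(seed: int = 0) -> PipelineConfig:
    """Study-shaped configuration at reduced per-block trial count.

    Keeps the trial's sample size (10 subjects, 3 crossover sessions,
    baseline + 4 hourly EEG timepoints) but runs 60 trials per block and
    15 s resting segments so a full simulate→analyze cycle stays in the
    minutes range; dose contrasts remain well powered at this scale.
    """
    return PipelineConfig(
        seed=seed,
        n_subjects=10,
        trials_per_block=60,
        n_oddball=6,
        resting_segment_s=15.0,
        n_resting_pairs=2,
    )


def demo_config(seed: int = 0) -> PipelineConfig:
    """Reduced desk-scale configuration: 4 subjects, 30 trials per block,
    short resting segments.  Runs end-to-end in minutes on one CPU."""
    return PipelineConfig(
        seed=seed,
        n_subjects=4,
        trials_per_block=30,
        n_oddball=3,
        resting_segment_s=15.0,
        n_resting_pairs=2,
    )
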