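"""Crossover session design: subjects, dose conditions, visits, timepoints.

Each subject attends three sessions (one per dose condition: placebo,
720 mg "low", 1440 mg "high").  The first-visit dose is randomized per
subject; the remaining two visits then follow a fixed rotation:

    visit 1 high    -> visit 2 placebo, visit 3 low
    visit 1 low     -> visit 2 high,    visit 3 placebo
    visit 1 placebo -> visit 2 low,     visit 3 high

Within a session, measurements are taken at a pretreatment baseline and
hourly post-dose timepoints (EEG analyzed over h1-h4, plasma metabolites
over h1-h5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PLACEBO = "placebo"
LOW = "low"
HIGH = "high"
DOSES = (PLACEBO, LOW, HIGH)
DOSE_MG = {PLACEBO: 0.0, LOW: 720.0, HIGH: 1440.0}

BASELINE = "baseline"
TIMEPOINTS = (BASELINE, "h1", "h2", "h3", "h4", "h5")
EEG_TIMEPOINTS = ("h1", "h2", "h3", "h4")
METABOLITE_TIMEPOINTS = ("h1", "h2", "h3", "h4", "h5")

# visit-1 dose -> doses of visits 2 and 3
_ROTATION = {
    HIGH: (PLACEBO, LOW),
    LOW: (HIGH, PLACEBO),
    PLACEBO: (LOW, HIGH),
}


@dataclass(frozen=True)
class SessionDesign:
    """One subject-session: who, which visit, which dose condition."""

    subject_id: str
    visit: int  # 1-based
    dose: str
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if self.dose not in DOSES:
            raise ValueError(f"unknown dose condition {self.dose!r}")
        if self.visit not in (1, 2, 3):
            raise ValueError("visit must be 1, 2 or 3")


def rotate_doses(first: str) -> tuple[str, str, str]:
    """Dose sequence over the three visits given the randomized first dose."""
    if first not in _ROTATION:
        raise ValueError(f"unknown dose condition {first!r}")
    second, third = _ROTATION[first]
    return (first, second, third)


def make_crossover_design(
    n_subjects: int,
    rng: np.random.Generator,
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> list[SessionDesign]:
    """Randomize the crossover: draw each subject's first dose, rotate the rest.

    Every subject receives every dose condition exactly once.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    sessions: list[SessionDesign] = []
    for i in range(n_subjects):
        subject_id = f"S{i + 1:02d}"
        first = DOSES[rng.integers(0, 3)]
        for visit, dose in enumerate(rotate_doses(first), start=1):
            sessions.append(
                SessionDesign(subject_id=subject_id, visit=visit, dose=dose,
                              timepoints=timepoints)
            )
    return sessions


def design_table(sessions: list[SessionDesign]) -> pd.DataFrame:
    """Long-format design table (one row per subject-session)."""
    return pd.DataFrame(
        [
            {"subject_id": s.subject_id, "visit": s.visit, "dose": s.dose}
            for s in sessions
        ]
    )
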