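"""One-compartment oral pharmacokinetics for plasma metabolite trajectories.

The drug (4-Cl-KYN) and its downstream kynurenine-pathway metabolites are
modelled with the Bateman function — first-order absorption (ka) feeding
first-order elimination (ke):

    C(t) = baseline * (1 + diurnal(t)) + scale * dose_mg * ka/(ka-ke)
           * (exp(-ke*t) - exp(-ka*t))

Defaults put the peak (tmax = ln(ka/ke)/(ka-ke)) in the 1-2 h window and the
terminal half-life (ln2/ke) in the 1.5-2 h window reported for this drug.
Endogenous metabolites carry a nonzero baseline with a slow diurnal cosine;
placebo sessions (dose_mg = 0) show baseline + diurnal only.  Measurement
noise is multiplicative log-normal with a configurable coefficient of
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: analytes assayed in plasma: prodrug, its two active metabolites, and the
#: endogenous kynurenine-pathway markers
ANALYTES = (
    "4-Cl-KYN",
    "7-Cl-KYNA",
    "4-Cl-3-HAA",
    "KYN",
    "KYNA",
    "3-HAA",
    "QUIN",
)


@dataclass(frozen=True)
class PKConfig:
    """Bateman-curve parameters for one analyte.

    ka, ke : 1/h
        Absorption and elimination rates; requires ka > ke > 0.
    scale : (ng/mL)/mg
        Dose-proportional peak scaling of the drug-derived component.
    baseline : ng/mL
        Endogenous concentration (zero for drug-derived analytes).
    diurnal_amplitude : fraction of baseline modulated by a 24 h cosine.
    diurnal_phase_h : hour of the diurnal peak relative to dosing.
    noise_cv : coefficient of variation of log-normal measurement noise.
    """

    ka: float = 2.0
    ke: float = float(np.log(2) / 1.75)
    scale: float = 0.05
    baseline: float = 0.0
    diurnal_amplitude: float = 0.0
    diurnal_phase_h: float = 3.0
    noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.ka == self.ke:
            raise ValueError("ka == ke: degenerate Bateman curve")
        if not (self.ka > self.ke > 0):
            raise ValueError("requires ka > ke > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def tmax(self) -> float:
        """Time of peak of the dose-derived component, hours."""
        return float(np.log(self.ka / self.ke) / (self.ka - self.ke))

    @property
    def half_life(self) -> float:
        """Terminal elimination half-life ln2/ke, hours."""
        return float(np.log(2) / self.ke)


def _default_analyte_configs() -> dict[str, PKConfig]:
    base = PKConfig()
    # drug-derived analytes: no endogenous baseline, dose-proportional;
    # scales set so condition means sit in the concentration ranges the
    # assay reports (prodrug in the 1e4 ng/mL range, metabolites lower)
    drug = {
        "4-Cl-KYN": replace(base, scale=18.0),
        "7-Cl-KYNA": replace(base, scale=0.12),
        "4-Cl-3-HAA": replace(base, scale=0.014),
    }
    # endogenous metabolites: baseline + diurnal drift; small or zero dose
    # response (KYN and QUIN do not respond to the drug)
    endo = {
        "KYN": replace(base, scale=0.0, baseline=300.0, diurnal_amplitude=0.08),
        "KYNA": replace(base, scale=0.003, baseline=6.0, diurnal_amplitude=0.10),
        "3-HAA": replace(base, scale=0.002, baseline=3.4, diurnal_amplitude=0.10),
        "QUIN": replace(base, scale=0.0, baseline=47.0, diurnal_amplitude=0.06),
    }
    return {**drug, **endo}


DEFAULT_ANALYTE_CONFIGS: dict[str, PKConfig] = _default_analyte_configs()


@dataclass
class MetaboliteSeries:
    """Concentration trajectory of one analyte in one session."""

    analyte: str
    times: np.ndarray  # hours post-dose, strictly increasing
    concentrations: np.ndarray  # ng/mL, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


def bateman(t: np.ndarray, ka: float, ke: float) -> np.ndarray:
    """Unit-dose Bateman curve ka/(ka-ke) * (exp(-ke t) - exp(-ka t))."""
    if ka == ke:
        raise ValueError("ka == ke: degenerate Bateman curve")
    t = np.asarray(t, dtype=float)
    return ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def metabolite_curve(pk: PKConfig, dose_mg: float, times: np.ndarray) -> np.ndarray:
    """Noiseless concentration curve: baseline, diurnal drift, Bateman term."""
    times = np.asarray(times, dtype=float)
    diurnal = pk.diurnal_amplitude * np.cos(
        2 * np.pi * (times - pk.diurnal_phase_h) / 24.0
    )
    curve = pk.baseline * (1.0 + diurnal) + pk.scale * dose_mg * bateman(
        times, pk.ka, pk.ke
    )
    return curve


def simulate_metabolite(
    analyte: str,
    dose_mg: float,
    pk: PKConfig,
    times: np.ndarray,
    rng: np.random.Generator,
) -> MetaboliteSeries:
    """Simulate one measured concentration trajectory.

    Multiplicative log-normal noise with CV ``pk.noise_cv`` is applied to the
    noiseless curve; any negative value (impossible under log-normal noise,
    possible only for degenerate inputs) is clipped at zero and logged.
    """
    times = np.asarray(times, dtype=float)
    if dose_mg < 0:
        raise ValueError("dose_mg must be non-negative")
    if np.any(times < 0) or np.any(times > 24):
        raise ValueError("times must lie within [0, 24] hours post-dose")
    curve = metabolite_curve(pk, dose_mg, times)
    if pk.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + pk.noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=times.shape)
        curve = curve * noise
    if np.any(curve < 0):
        logger.warning(
            "%s: %d negative concentrations clipped to 0",
            analyte,
            int(np.sum(curve < 0)),
        )
        curve = np.clip(curve, 0.0, None)
    return MetaboliteSeries(analyte=analyte, times=times, concentrations=curve)
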