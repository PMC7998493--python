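"""Resting metabolic rate, MET-based activity level, and the Goldberg screen.

The revised Goldberg cut-off (as formulated by Black) brackets the
plausible range of the reported-energy-intake to RMR ratio around the
population PAL:

    low/high = PAL * exp(-+ z * S / 100),
    S = sqrt(CV_wEI^2 / d + CV_wB^2 + CV_tP^2)

where d is the number of diary days, CV_wEI the within-subject variation
of energy intake, CV_wB the repeatability CV of metabolic-rate
measurement and CV_tP the between-subject variation in PAL (all in
percent).  Subjects whose EI:RMR ratio falls below/above the band are
low/high energy reporters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "MUELLER_RMR_COEFFICIENTS",
    "ActivityDiary",
    "EnergyScreenResult",
    "rmr_mueller",
    "pal_from_diary",
    "goldberg_cutoffs",
    "classify_reporting",
    "screen_energy",
]

#: Default adult RMR equation coefficients (MJ/d), overridable per call:
#: RMR = a_mass * mass_kg + a_sex * sex + a_age * age_y + intercept,
#: sex coded 1 = male, 0 = female.
MUELLER_RMR_COEFFICIENTS = {
    "mass": 0.047,
    "sex": 1.009,
    "age": -0.01452,
    "intercept": 3.21,
}

#: Light-effort MET assumed for unrecorded time; sleep MET per the
#: Compendium of Physical Activities.
DEFAULT_FILLER_MET = 1.4
SLEEP_MET = 0.95

MINUTES_PER_DAY = 1440.0


def rmr_mueller(
    body_mass: float,
    age: float,
    sex: int,
    coefficients: dict[str, float] | None = None,
) -> float:
    """Resting metabolic rate in MJ/d from a linear mass/age/sex equation.

    Strictly increasing in body mass.  ``sex``: 0 = female, 1 = male.
    """
    if body_mass <= 0 or age <= 0:
        raise ValueError("body mass and age must be positive")
    if sex not in (0, 1):
        raise ValueError("sex must be 0 (female) or 1 (male)")
    c = coefficients or MUELLER_RMR_COEFFICIENTS
    for key in ("mass", "sex", "age", "intercept"):
        if key not in c:
            raise KeyError(f"RMR coefficient set lacks {key!r}")
    return c["mass"] * body_mass + c["sex"] * sex + c["age"] * age + c["intercept"]


@dataclass
class ActivityDiary:
    """MET x minutes entries for one day; unrecorded time fills at MET 1.4."""

    entries: list[tuple[float, float]] = field(default_factory=list)
    filler_met: float = DEFAULT_FILLER_MET

    def __post_init__(self) -> None:
        total = 0.0
        for met, minutes in self.entries:
            if met <= 0 or minutes <= 0:
                raise ValueError("MET and minutes must be positive")
            total += minutes
        if total > MINUTES_PER_DAY:
            raise ValueError(f"diary exceeds one day: {total} min")


def pal_from_diary(diary: ActivityDiary, rmr: float) -> float:
    """Physical activity level = total energy expenditure / RMR.

    TEE sums MET x (RMR per minute) x minutes over the diary plus the
    filler MET for the remaining time, so the PAL is the time-weighted
    mean MET and is independent of the RMR value itself.
    """
    if rmr <= 0:
        raise ValueError("RMR must be positive")
    recorded = sum(minutes for _, minutes in diary.entries)
    met_minutes = sum(met * minutes for met, minutes in diary.entries)
    met_minutes += diary.filler_met * (MINUTES_PER_DAY - recorded)
    return met_minutes / MINUTES_PER_DAY


def goldberg_cutoffs(
    pal: float,
    d: int,
    cv_wEI: float = 23.0,
    cv_wB: float = 8.5,
    cv_tP: float = 15.0,
    z: float = 1.96,
) -> tuple[float, float]:
    """Goldberg/Black plausibility band for the EI:RMR ratio.

    CVs in percent; defaults are the conventional values for diary-based
    intake (23%), repeated metabolic-rate measurement (8.5%) and
    between-subject PAL variation (15%).
    """
    if d < 1:
        raise ValueError("d must be at least 1 diary day")
    if min(cv_wEI, cv_wB, cv_tP) < 0:
        raise ValueError("CVs must be non-negative")
    s = math.sqrt(cv_wEI**2 / d + cv_wB**2 + cv_tP**2)
    return pal * math.exp(-z * s / 100.0), pal * math.exp(z * s / 100.0)


def classify_reporting(
    energy_intake: float, rmr: float, cutoffs: tuple[float, float]
) -> str:
    """'low' | 'plausible' | 'high' from the EI:RMR ratio vs the band."""
    if rmr <= 0:
        raise ValueError("RMR must be positive")
    ratio = energy_intake / rmr
    low, high = cutoffs
    if ratio < low:
        return "low"
    if ratio > high:
        return "high"
    return "plausible"


@dataclass
class EnergyScreenResult:
    rmr: float
    pal: float
    ei_rmr_ratio: float
    cutoff_low: float
    cutoff_high: float
    reporter_class: str
    sdev_total: float  # the combined CV term S, percent


def screen_energy(
    energy_intake: float,
    body_mass: float,
    age: float,
    sex: int,
    pal: float,
    *,
    d: int = 3,
    cv_wEI: float = 23.0,
    cv_wB: float = 8.5,
    cv_tP: float = 15.0,
    z: float = 1.96,
    rmr_coefficients: dict[str, float] | None = None,
) -> EnergyScreenResult:
    """Full misreporting screen for one subject-visit.

    ``energy_intake`` in MJ/d on the same scale as the RMR equation.
    """
    rmr = rmr_mueller(body_mass, age, sex, rmr_coefficients)
    low, high = goldberg_cutoffs(pal, d, cv_wEI, cv_wB, cv_tP, z)
    s = math.sqrt(cv_wEI**2 / d + cv_wB**2 + cv_tP**2)
    return EnergyScreenResult(
        rmr=rmr,
        pal=pal,
        ei_rmr_ratio=energy_intake / rmr,
        cutoff_low=low,
        cutoff_high=high,
        reporter_class=classify_reporting(energy_intake, rmr, (low, high)),
        sdev_total=s,
    )
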