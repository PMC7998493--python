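"""Closed-form biological-variation metrics.

Implements the standard within/between-subject coefficient-of-variation
algebra for serially measured biomarkers:

* lognormal CV <-> log-scale SD conversion, ``sigma = sqrt(ln(CV^2 + 1))``
  and its inverse ``CV = sqrt(exp(sigma^2) - 1)``;
* the index of individuality ``II = CV_T / CV_G`` with the conventional
  0.6 / 1.4 interpretation thresholds;
* reference change values (RCV), symmetric ``Z * sqrt(2) * CV_T`` on the
  raw scale and asymmetric up/down under a lognormal model;
* the number of repeated measurements ``n_beta = [P/(1-P)] * S_w^2/S_b^2``
  that confines regression-dilution attenuation of a slope to ``1 - P``;
* ICC interpretation bands and the Fisher-transform ICC sample-size
  formula (Walter/Eliasziw/Donner form).

All CVs are fractions of the mean (0.113, not 11.3%); RCVs are returned
in percent because that is how they are read clinically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .variance_models import ICCResult, VarianceComponents

__all__ = [
    "sigma_from_cv",
    "cv_from_sigma",
    "cv_from_components",
    "index_of_individuality",
    "individuality_class",
    "rcv_symmetric",
    "rcv_asymmetric",
    "n_measurements",
    "n_measurements_from_icc",
    "icc_category",
    "icc_sample_size",
    "SampleSizeParams",
    "RCV",
    "ReliabilityRow",
]


def sigma_from_cv(cv: float) -> float:
    """Log-scale standard deviation of a lognormal variable with CV ``cv``.

    ``sigma = sqrt(ln(cv^2 + 1))``; exact inverse of :func:`cv_from_sigma`.
    """
    if cv < 0:
        raise ValueError(f"CV must be non-negative, got {cv}")
    return math.sqrt(math.log1p(cv * cv))


def cv_from_sigma(sigma: float) -> float:
    """Original-scale CV of a lognormal variable with log-scale SD ``sigma``."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    return math.sqrt(math.expm1(sigma * sigma))


def cv_from_components(vc: VarianceComponents) -> tuple[float, float]:
    """Between-subject and within-subject CVs from fitted variance components.

    On the log scale each component's SD is converted through the lognormal
    relation; on the raw scale CV = SD / grand mean.

    Returns
    -------
    (cv_g, cv_t)
        Inter-individual and total intra-individual CV as fractions.
    """
    if vc.scale == "log":
        cv_g = cv_from_sigma(math.sqrt(vc.sigma2_between))
        cv_t = cv_from_sigma(math.sqrt(vc.sigma2_within))
    else:
        if vc.grand_mean <= 0:
            raise ValueError(
                "raw-scale CV requires a positive grand mean, "
                f"got {vc.grand_mean}"
            )
        cv_g = math.sqrt(vc.sigma2_between) / vc.grand_mean
        cv_t = math.sqrt(vc.sigma2_within) / vc.grand_mean
    return cv_g, cv_t


def index_of_individuality(cv_t: float, cv_g: float) -> Optional[float]:
    """``II = CV_T / CV_G``; ``None`` (undefined) when CV_G is zero.

    II < 0.6 marks high individuality (population reference intervals are
    insensitive to individual change; use the RCV instead); II > 1.4 marks
    low individuality.
    """
    if cv_t < 0 or cv_g < 0:
        raise ValueError("CVs must be non-negative")
    if cv_g == 0:
        return None
    return cv_t / cv_g


def individuality_class(ii: Optional[float]) -> str:
    if ii is None:
        return "undefined"
    if ii < 0.6:
        return "high_individuality"
    if ii > 1.4:
        return "low_individuality"
    return "intermediate"


def rcv_symmetric(cv_t: float, z: float = 1.96) -> float:
    """Symmetric reference change value in percent: ``z * sqrt(2) * CV_T * 100``."""
    if cv_t < 0:
        raise ValueError("CV must be non-negative")
    if z <= 0:
        raise ValueError("z must be positive")
    return z * math.sqrt(2.0) * cv_t * 100.0


def rcv_asymmetric(cv_t: float, z: float = 1.96) -> tuple[float, float]:
    """Asymmetric (up, down) reference change values in percent.

    Lognormal model: ``RCV = (exp(+-z * sqrt(2) * sigma) - 1) * 100`` with
    ``sigma = sqrt(ln(CV_T^2 + 1))``.  The upward RCV always exceeds the
    magnitude of the downward one.
    """
    if cv_t < 0:
        raise ValueError("CV must be non-negative")
    sigma = sigma_from_cv(cv_t)
    half_width = z * math.sqrt(2.0) * sigma
    return (math.expm1(half_width) * 100.0, math.expm1(-half_width) * 100.0)


def _round_excess(raw: float, excess: float = 0.20) -> int:
    """Round down unless the fractional part exceeds ``excess``; floor at 1."""
    lower = math.floor(raw)
    n = lower + 1 if raw - lower > excess else lower
    return max(n, 1)


def n_measurements(
    s_w2: float, s_b2: float, attenuation: float
) -> Optional[int]:
    """Measurements per subject limiting slope attenuation to ``attenuation``.

    ``n_beta = [P/(1-P)] * S_w^2 / S_b^2`` with ``P = 1 - attenuation``.
    Rounded to the lower integer unless the fractional excess is more than
    0.20, floored at one measurement.  Undefined (``None``) when the
    between-subject variance is zero.
    """
    if s_w2 <= 0:
        raise ValueError("within-subject variance must be positive")
    if not 0 < attenuation < 1:
        raise ValueError("attenuation must lie in (0, 1)")
    if s_b2 < 0:
        raise ValueError("between-subject variance must be non-negative")
    if s_b2 == 0:
        return None
    p = 1.0 - attenuation
    raw = (p / (1.0 - p)) * (s_w2 / s_b2)
    return _round_excess(raw)


def n_measurements_from_icc(icc: float, attenuation: float) -> Optional[int]:
    """Same as :func:`n_measurements` parameterized by the ICC.

    ``S_w^2/S_b^2 = (1 - ICC)/ICC``, so the printed ICC of a reliability
    table is sufficient to reproduce its n_beta columns.
    """
    if not 0 <= icc <= 1:
        raise ValueError("ICC must lie in [0, 1]")
    if icc == 0:
        return None
    return n_measurements(1.0 - icc if icc < 1 else 1e-300, icc, attenuation)


def icc_category(icc: float) -> str:
    """Reliability band: very_good (>=0.75), good (0.51-0.74), fair
    (0.40-0.50), poor (<0.40).

    Values strictly between 0.50 and 0.51 fall outside the quoted bands;
    they are assigned to *fair* and a warning is emitted.
    """
    if not 0 <= icc <= 1:
        raise ValueError("ICC must lie in [0, 1]")
    if icc >= 0.75:
        return "very_good"
    if icc >= 0.51:
        return "good"
    if icc >= 0.40:
        if icc > 0.50:
            warnings.warn(
                f"ICC {icc:.4f} falls in the (0.50, 0.51) gap between the "
                "'fair' and 'good' bands; classified as fair",
                stacklevel=2,
            )
        return "fair"
    return "poor"


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs to the ICC sample-size formula."""

    rho1: float
    rho0: float = 0.0
    k: int = 3
    alpha: float = 0.05
    tails: int = 2
    power: float = 0.80
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.rho1 < 1:
            raise ValueError("rho1 must lie in (0, 1)")
        if not 0 <= self.rho0 < 1:
            raise ValueError("rho0 must lie in [0, 1)")
        if self.rho1 <= self.rho0:
            raise ValueError("rho1 must exceed rho0")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def icc_sample_size(params: SampleSizeParams) -> dict[str, float]:
    """Subjects needed to detect ICC ``rho1`` against ``rho0`` with ``k`` repeats.

    Fisher-transform form::

        n = 1 + 2 k (z_alpha + z_power)^2 / [(k - 1) (ln C)^2],
        C = (1 + k theta_1) / (1 + k theta_0),  theta = rho / (1 - rho)

    rounded up to an integer; the dropout-inflated size multiplies by
    ``(1 + dropout)`` before the ceiling.

    Returns a dict with ``n_raw`` (pre-ceiling), ``n_required`` and
    ``n_with_dropout``.
    """
    p = params
    z_alpha = stats.norm.ppf(1.0 - p.alpha / p.tails)
    z_power = stats.norm.ppf(p.power)
    theta1 = p.rho1 / (1.0 - p.rho1)
    theta0 = p.rho0 / (1.0 - p.rho0)
    c = (1.0 + p.k * theta1) / (1.0 + p.k * theta0)
    n_raw = 1.0 + 2.0 * p.k * (z_alpha + z_power) ** 2 / (
        (p.k - 1) * math.log(c) ** 2
    )
    n_required = math.ceil(n_raw - 1e-12)
    n_with_dropout = math.ceil(n_required * (1.0 + p.dropout) - 1e-12)
    return {
        "n_raw": n_raw,
        "n_required": n_required,
        "n_with_dropout": n_with_dropout,
    }


@dataclass
class RCV:
    """Reference change value: symmetric (+-) or asymmetric (up, down) percents."""

    symmetric: Optional[float] = None
    up: Optional[float] = None
    down: Optional[float] = None

    @property
    def is_symmetric(self) -> bool:
        return self.symmetric is not None


@dataclass
class ReliabilityRow:
    """One biomarker's reliability summary (one row of the report table)."""

    biomarker: str
    n_subjects: int
    icc_crude: ICCResult
    cv_g: float
    cv_t: float
    ii: Optional[float]
    rcv: RCV
    n_beta_10: Optional[int]
    n_beta_20: Optional[int]
    category: str
    scale: str = "log"
    icc_adjusted: Optional[ICCResult] = None
    singular: bool = False
    excluded_subjects: list = field(default_factory=list)
    notes: str = ""


def build_reliability_row(
    biomarker: str,
    fit,
    icc_crude: ICCResult,
    *,
    z: float = 1.96,
    attenuation_levels: tuple[float, float] = (0.10, 0.20),
    icc_adjusted: Optional[ICCResult] = None,
    excluded_subjects: Optional[list] = None,
    notes: str = "",
) -> ReliabilityRow:
    """Assemble a report row from a crude one-way fit and its bootstrap CI.

    The CVs, II, RCV and n_beta columns are all derived from the crude
    variance components; the RCV is symmetric for raw-scale biomarkers and
    asymmetric (lognormal) for log-scale ones.
    """
    vc = fit.components
    cv_g, cv_t = cv_from_components(vc)
    ii = index_of_individuality(cv_t, cv_g)
    if vc.scale == "log":
        up, down = rcv_asymmetric(cv_t, z)
        rcv = RCV(up=up, down=down)
    else:
        rcv = RCV(symmetric=rcv_symmetric(cv_t, z))
    if vc.sigma2_within > 0 and vc.sigma2_between > 0:
        n10 = n_measurements(vc.sigma2_within, vc.sigma2_between, attenuation_levels[0])
        n20 = n_measurements(vc.sigma2_within, vc.sigma2_between, attenuation_levels[1])
    else:
        n10 = n20 = None
    return ReliabilityRow(
        biomarker=biomarker,
        n_subjects=fit.n_subjects_used,
        icc_crude=icc_crude,
        cv_g=cv_g,
        cv_t=cv_t,
        ii=ii,
        rcv=rcv,
        n_beta_10=n10,
        n_beta_20=n20,
        category=icc_category(icc_crude.icc),
        scale=vc.scale,
        icc_adjusted=icc_adjusted,
        singular=vc.singular,
        excluded_subjects=list(excluded_subjects or []),
        notes=notes,
    )
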