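"""Synthetic repeated-measures cohorts with known variance structure.

The study whose design this package analyses did not deposit its data, so
every downstream stage is exercised on simulated cohorts with *known*
inter-/intra-individual variance structure.  A biomarker is generated
from a random-intercept model on its analysis scale:

* lognormal: ``ln y_ij = ln(mu) + sum(slope * x_ij) + b_i + e_ij`` with
  ``b_i ~ N(0, sigma_b^2)``, ``e_ij ~ N(0, sigma_w^2)`` and the sigmas
  obtained from the target CVs through ``sigma = sqrt(ln(CV^2 + 1))``;
* normal (raw scale): ``y_ij = mu + sum(slope * x_ij) + b_i + e_ij`` with
  SDs ``cv * mu``.

Covariate effects therefore act on the analysis scale, so the adjusted
mixed model is correctly specified under simulation and parameter
recovery can be tested exactly.  Each biomarker and each covariate draws
from its own seed substream keyed by name, so adding a column never
perturbs the others.  Aberrant subjects are injected separately
(:func:`inject_outliers`) by inflating within-subject spread or shifting
a subject's mean, to exercise the Cochran/Reed/residual screens.

The default spec mirrors the magnitudes of a published reliability table
for 17 antioxidant-status biomarkers in premenopausal women (44 subjects,
3 visits ~28 days apart).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort_io import MeasurementTable
from .reliability_metrics import sigma_from_cv

__all__ = [
    "BiomarkerSpec",
    "CovariateSpec",
    "OutlierInjection",
    "SyntheticSpec",
    "generate_cohort",
    "inject_outliers",
    "true_params",
    "default_cohort_spec",
    "spec_from_yaml",
    "spec_to_yaml",
]


@dataclass
class BiomarkerSpec:
    """Target mean and CV structure for one biomarker.

    ``effects`` maps covariate name -> slope on the analysis scale (log
    scale for lognormal biomarkers, original units otherwise).
    """

    mu: float
    cv_g: float
    cv_t: float
    lognormal: bool = True
    effects: dict[str, float] = field(default_factory=dict)
    unit: str = ""

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.cv_g < 0 or self.cv_t < 0:
            raise ValueError("CVs must be non-negative")

    def sigmas(self) -> tuple[float, float]:
        """(sigma_b, sigma_w) on the analysis scale."""
        if self.lognormal:
            return sigma_from_cv(self.cv_g), sigma_from_cv(self.cv_t)
        return self.cv_g * self.mu, self.cv_t * self.mu


@dataclass
class CovariateSpec:
    """Between/within decomposition of a covariate, or a Bernoulli flag."""

    mean: float = 0.0
    sd_between: float = 0.0
    sd_within: float = 0.0
    bernoulli_p: Optional[float] = None


@dataclass
class OutlierInjection:
    subject: int  # 0-based subject index
    kind: str  # "variance_inflation" | "mean_shift"
    magnitude: float
    biomarker: Optional[str] = None  # None = all biomarkers

    def __post_init__(self) -> None:
        if self.kind not in ("variance_inflation", "mean_shift"):
            raise ValueError(f"unknown injection kind {self.kind!r}")
        if self.kind == "variance_inflation" and self.magnitude <= 1:
            raise ValueError("variance_inflation magnitude must exceed 1")


@dataclass
class SyntheticSpec:
    biomarkers: dict[str, BiomarkerSpec]
    n_subjects: int = 44
    n_visits: int = 3
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)
    outliers: list[OutlierInjection] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_visits < 2:
            raise ValueError("need n_subjects >= 2 and n_visits >= 2")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent substream keyed by a stable hash of ``label``."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _covariate_matrix(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Draw each covariate as an (n_subjects, n_visits) array."""
    n, k = spec.n_subjects, spec.n_visits
    out = {}
    for name, cs in spec.covariates.items():
        rng = _stream(spec.seed, f"covariate:{name}")
        if cs.bernoulli_p is not None:
            subject = rng.binomial(1, cs.bernoulli_p, size=n).astype(float)
            out[name] = np.repeat(subject[:, None], k, axis=1)
        else:
            subject = cs.mean + cs.sd_between * rng.standard_normal(n)
            within = cs.sd_within * rng.standard_normal((n, k))
            out[name] = subject[:, None] + within
    return out


def generate_cohort(spec: SyntheticSpec) -> MeasurementTable:
    """Simulate a cohort; deterministic given ``spec.seed``.

    Injections listed in ``spec.outliers`` are *not* applied here; pass
    the result through :func:`inject_outliers` to add aberrant subjects.
    """
    n, k = spec.n_subjects, spec.n_visits
    covs = _covariate_matrix(spec)
    data = {
        "subject": np.repeat([f"S{i+1:03d}" for i in range(n)], k),
        "visit": np.tile(np.arange(1, k + 1), n),
    }
    for name, bs in spec.biomarkers.items():
        rng = _stream(spec.seed, f"biomarker:{name}")
        sigma_b, sigma_w = bs.sigmas()
        if not np.isfinite(sigma_b) or not np.isfinite(sigma_w):
            raise ValueError(f"CV for {name!r} produces non-finite variance")
        b = sigma_b * rng.standard_normal(n)
        e = sigma_w * rng.standard_normal((n, k))
        eta = b[:, None] + e
        for cov, slope in bs.effects.items():
            if cov not in covs:
                raise KeyError(f"effect on unknown covariate {cov!r} for {name!r}")
            eta = eta + slope * covs[cov]
        if bs.lognormal:
            y = np.exp(np.log(bs.mu) + eta)
        else:
            # A normal model with a large CV has small but nonzero mass below
            # zero; censor at a detection-limit floor, as an assay would.
            y = np.maximum(bs.mu + eta, bs.mu * 1e-3)
        data[name] = y.reshape(-1)
    for name, x in covs.items():
        data[name] = x.reshape(-1)
    return MeasurementTable(
        data=pd.DataFrame(data),
        biomarkers=list(spec.biomarkers),
        covariates=list(covs),
        n_visits=k,
        units={name: bs.unit for name, bs in spec.biomarkers.items()},
    )


def inject_outliers(table: MeasurementTable, spec: SyntheticSpec) -> MeasurementTable:
    """Apply the spec's outlier injections; untouched records unchanged.

    ``variance_inflation`` multiplies a subject's within-subject deviations
    (about its own mean, on the analysis scale) by the magnitude;
    ``mean_shift`` adds magnitude x sigma_b (analysis scale) to all of the
    subject's values.
    """
    if not spec.outliers:
        return table
    df = table.data.copy()
    subjects = list(pd.unique(df["subject"]))
    for inj in spec.outliers:
        if not 0 <= inj.subject < len(subjects):
            raise IndexError(f"no subject with index {inj.subject}")
        sid = subjects[inj.subject]
        mask = (df["subject"] == sid).to_numpy()
        targets = [inj.biomarker] if inj.biomarker else list(table.biomarkers)
        for name in targets:
            if name not in table.biomarkers:
                raise KeyError(f"unknown biomarker {name!r}")
            bs = spec.biomarkers[name]
            vals = df.loc[mask, name].to_numpy(dtype=float)
            x = np.log(vals) if bs.lognormal else vals
            if inj.kind == "variance_inflation":
                x = x.mean() + inj.magnitude * (x - x.mean())
            else:  # mean_shift
                sigma_b, _ = bs.sigmas()
                x = x + inj.magnitude * sigma_b
            df.loc[mask, name] = np.exp(x) if bs.lognormal else x
    return MeasurementTable(
        data=df,
        biomarkers=list(table.biomarkers),
        covariates=list(table.covariates),
        n_visits=table.n_visits,
        units=dict(table.units),
    )


def true_params(spec: SyntheticSpec) -> dict[str, dict[str, float]]:
    """Ground-truth ICC and CVs per biomarker (analysis scale)."""
    out = {}
    for name, bs in spec.biomarkers.items():
        sigma_b, sigma_w = bs.sigmas()
        v_b, v_w = sigma_b**2, sigma_w**2
        icc = 1.0 if v_w == 0 else v_b / (v_b + v_w) if (v_b + v_w) > 0 else 0.0
        out[name] = {"icc": icc, "cv_g": bs.cv_g, "cv_t": bs.cv_t}
    return out


# Published magnitudes: baseline medians (Table-1 scale) and the crude
# between/within CV pairs of the reliability table; log transform for all
# biomarkers except bilirubin, eCAT, glutathione and TEAC.
_DEFAULT_BIOMARKERS: dict[str, tuple[float, float, float, bool, str]] = {
    #                 mu      cv_g   cv_t   lognormal  unit
    "bilirubin": (7.27, 0.343, 0.299, False, "µmol/L"),
    "uric_acid": (238.0, 0.170, 0.113, True, "µmol/L"),
    "vitamin_c": (94.0, 0.127, 0.123, True, "µmol/L"),
    "alpha_tocopherol": (20.4, 0.169, 0.110, True, "µmol/L"),
    "gamma_tocopherol": (1030.0, 0.409, 0.310, True, "nmol/L"),
    "retinol": (2040.0, 0.191, 0.186, True, "nmol/L"),
    "alpha_carotene": (340.0, 0.547, 0.266, True, "nmol/L"),
    "beta_carotene": (890.0, 0.617, 0.217, True, "nmol/L"),
    "lutein": (210.0, 0.336, 0.227, True, "nmol/L"),
    "zeaxanthin": (110.0, 0.333, 0.323, True, "nmol/L"),
    "beta_cryptoxanthin": (220.0, 0.378, 0.209, True, "nmol/L"),
    "lycopene": (740.0, 0.385, 0.248, True, "nmol/L"),
    "coenzyme_q10": (515.0, 0.300, 0.166, True, "nmol/L"),
    "glutathione": (656.0, 0.053, 0.161, False, "µmol/L"),
    "ecat": (638.0, 0.083, 0.060, False, "kU/gHb"),
    "egpx": (24.5, 0.236, 0.130, True, "U/gHb"),
    "teac": (1.11, 0.000, 0.070, False, "mmol/L"),
}

_DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "cycle_day": CovariateSpec(mean=15.0, sd_between=5.0, sd_within=6.0),
    "bmi": CovariateSpec(mean=21.8, sd_between=2.5, sd_within=0.3),
    "fasting_h": CovariateSpec(mean=13.2, sd_between=0.5, sd_within=0.6),
    "sleep_h": CovariateSpec(mean=8.0, sd_between=0.5, sd_within=0.6),
    "contraceptive": CovariateSpec(bernoulli_p=0.5),
    "cholesterol": CovariateSpec(mean=3.9, sd_between=0.55, sd_within=0.2),
    "pal": CovariateSpec(mean=1.6, sd_between=0.10, sd_within=0.05),
    "energy_mj": CovariateSpec(mean=8.1, sd_between=1.4, sd_within=1.1),
    "vitamin_c_intake": CovariateSpec(mean=150.0, sd_between=60.0, sd_within=50.0),
    "tocopherol_intake": CovariateSpec(mean=14.0, sd_between=4.5, sd_within=3.5),
    "retinol_intake": CovariateSpec(mean=1.5, sd_between=0.6, sd_within=0.5),
    "beta_carotene_intake": CovariateSpec(mean=6.0, sd_between=3.5, sd_within=3.0),
    "purine_intake": CovariateSpec(mean=120.0, sd_between=28.0, sd_within=22.0),
    "analgesic": CovariateSpec(bernoulli_p=5 / 44),
    "vaccination": CovariateSpec(bernoulli_p=1 / 44),
    "abnormal_cycle": CovariateSpec(bernoulli_p=3 / 44),
    "health_problem": CovariateSpec(bernoulli_p=6 / 44),
    "hs_crp": CovariateSpec(mean=12.0, sd_between=9.0, sd_within=5.0),
}


def default_cohort_spec(
    seed: int = 0, n_subjects: int = 44, n_visits: int = 3
) -> SyntheticSpec:
    """The demo/testing spec: 17 biomarkers at published CV magnitudes,
    44 subjects x 3 visits, standard covariates, no injected outliers."""
    biomarkers = {
        name: BiomarkerSpec(mu=mu, cv_g=cg, cv_t=ct, lognormal=ln, unit=unit)
        for name, (mu, cg, ct, ln, unit) in _DEFAULT_BIOMARKERS.items()
    }
    return SyntheticSpec(
        biomarkers=biomarkers,
        n_subjects=n_subjects,
        n_visits=n_visits,
        covariates=dict(_DEFAULT_COVARIATES),
        seed=seed,
    )


def spec_to_yaml(spec: SyntheticSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


def spec_from_yaml(path) -> SyntheticSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["biomarkers"] = {
        k: BiomarkerSpec(**v) for k, v in raw.get("biomarkers", {}).items()
    }
    raw["covariates"] = {
        k: CovariateSpec(**v) for k, v in raw.get("covariates", {}).items()
    }
    raw["outliers"] = [OutlierInjection(**o) for o in raw.get("outliers", [])]
    return SyntheticSpec(**raw)
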