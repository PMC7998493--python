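"""Reading, validating and writing long-format repeated-measures cohorts.

The canonical container is :class:`MeasurementTable`: a tidy pandas
DataFrame with one row per subject x visit, biomarker concentration
columns (strictly positive or missing) and covariate columns, plus the
lists that say which column is which.  Units are carried as metadata
strings and never converted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementTable",
    "AnalysisConfig",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "wide_to_long",
    "write_reliability_report",
    "read_reliability_report",
]

#: Covariate columns recognized by default when reading a bare CSV.
DEFAULT_COVARIATES = (
    "cycle_day",
    "bmi",
    "fasting_h",
    "sleep_h",
    "contraceptive",
    "cholesterol",
    "pal",
    "energy_mj",
    "vitamin_c_intake",
    "tocopherol_intake",
    "retinol_intake",
    "beta_carotene_intake",
    "purine_intake",
    "analgesic",
    "vaccination",
    "abnormal_cycle",
    "health_problem",
    "hs_crp",
)

#: Published per-biomarker transform choices: natural log for all except
#: the four analyzed on the raw scale.
DEFAULT_LOG_TRANSFORM = {
    "bilirubin": False,
    "uric_acid": True,
    "vitamin_c": True,
    "alpha_tocopherol": True,
    "gamma_tocopherol": True,
    "retinol": True,
    "alpha_carotene": True,
    "beta_carotene": True,
    "lutein": True,
    "zeaxanthin": True,
    "beta_cryptoxanthin": True,
    "lycopene": True,
    "coenzyme_q10": True,
    "glutathione": False,
    "ecat": False,
    "egpx": True,
    "teac": False,
}

#: Biomarker-specific dietary covariate used in the adjusted model
#: (energy intake otherwise).
INTAKE_COVARIATES = {
    "uric_acid": "purine_intake",
    "vitamin_c": "vitamin_c_intake",
    "alpha_tocopherol": "tocopherol_intake",
    "gamma_tocopherol": "tocopherol_intake",
    "retinol": "retinol_intake",
    "alpha_carotene": "beta_carotene_intake",
    "beta_carotene": "beta_carotene_intake",
    "lutein": "beta_carotene_intake",
    "zeaxanthin": "beta_carotene_intake",
    "beta_cryptoxanthin": "beta_carotene_intake",
    "lycopene": "beta_carotene_intake",
}

COMMON_COVARIATES = (
    "cycle_day",
    "bmi",
    "fasting_h",
    "sleep_h",
    "contraceptive",
    "cholesterol",
    "pal",
)


class CohortValidationError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Run configuration for the reliability pipeline."""

    transform: dict[str, bool] = field(default_factory=dict)
    z: float = 1.96
    attenuation_levels: tuple[float, float] = (0.10, 0.20)
    n_boot: int = 2000
    residual_cutoff: float = 2.0
    cochran_alpha: float = 0.05
    cochran_bonferroni: bool = True
    iterative_screen: bool = True
    bootstrap_method: str = "percentile"
    seed: int = 0
    loq: dict[str, float] = field(default_factory=dict)
    common_covariates: tuple[str, ...] = COMMON_COVARIATES
    intake_covariates: dict[str, str] = field(
        default_factory=lambda: dict(INTAKE_COVARIATES)
    )
    energy_covariate: str = "energy_mj"

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("Z must be positive")
        if not all(0 < p < 1 for p in self.attenuation_levels):
            raise ValueError("attenuation levels must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        if self.residual_cutoff <= 0:
            raise ValueError("residual cutoff must be positive")
        if not 0 < self.cochran_alpha < 1:
            raise ValueError("Cochran alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "attenuation_levels" in raw:
            raw["attenuation_levels"] = tuple(raw["attenuation_levels"])
        if "common_covariates" in raw:
            raw["common_covariates"] = tuple(raw["common_covariates"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["attenuation_levels"] = list(self.attenuation_levels)
        d["common_covariates"] = list(self.common_covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def covariates_for(self, biomarker: str, available: Sequence[str]) -> list[str]:
        """Adjusted-model covariate list: common set plus the biomarker's
        dietary covariate (falling back to energy intake), restricted to
        the columns actually present."""
        intake = self.intake_covariates.get(biomarker, self.energy_covariate)
        wanted = list(self.common_covariates) + [intake]
        return [c for c in wanted if c in available]


@dataclass
class MeasurementTable:
    """Tidy subject x visit table with declared biomarker/covariate columns."""

    data: pd.DataFrame
    biomarkers: list[str]
    covariates: list[str] = field(default_factory=list)
    n_visits: int = 3
    units: dict[str, str] = field(default_factory=dict)
    loq_substitutions: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in ("subject", "visit"):
            if col not in df.columns:
                raise CohortValidationError(f"missing required column {col!r}")
        dup = df.duplicated(subset=["subject", "visit"])
        if dup.any():
            pairs = df.loc[dup, ["subject", "visit"]].values.tolist()
            raise CohortValidationError(f"duplicate (subject, visit) pairs: {pairs}")
        visits = df["visit"].to_numpy()
        if not np.issubdtype(np.asarray(visits).dtype, np.number):
            raise CohortValidationError("visit column must be numeric")
        if (visits < 1).any() or (visits > self.n_visits).any():
            raise CohortValidationError(
                f"visit indices must lie in 1..{self.n_visits}"
            )
        for b in self.biomarkers:
            if b not in df.columns:
                raise CohortValidationError(f"declared biomarker {b!r} absent")
            vals = df[b]
            if (vals.dropna() <= 0).any():
                raise CohortValidationError(
                    f"biomarker {b!r} has non-positive values"
                )
        if "contraceptive" in df.columns:
            vals = df["contraceptive"].dropna().unique()
            if not set(np.asarray(vals, dtype=float)).issubset({0.0, 1.0}):
                raise CohortValidationError(
                    "covariate 'contraceptive' must be binary {0,1}"
                )

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.data["subject"].to_numpy())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subset_subjects(self, subjects) -> "MeasurementTable":
        mask = self.data["subject"].isin(list(subjects))
        return MeasurementTable(
            data=self.data.loc[mask].reset_index(drop=True),
            biomarkers=list(self.biomarkers),
            covariates=list(self.covariates),
            n_visits=self.n_visits,
            units=dict(self.units),
            loq_substitutions=self.loq_substitutions,
        )

    def drop_subjects(self, subjects) -> "MeasurementTable":
        keep = [s for s in self.subjects if s not in set(subjects)]
        return self.subset_subjects(keep)


def read_cohort(
    path,
    config: Optional[AnalysisConfig] = None,
    *,
    covariates: Optional[Sequence[str]] = None,
    n_visits: Optional[int] = None,
) -> MeasurementTable:
    """Read and validate a long-format cohort CSV.

    Columns other than ``subject``/``visit`` are classified as covariates
    if named in ``covariates`` (default: the standard covariate names) and
    as biomarkers otherwise.  LOQ substitution from ``config.loq`` is
    applied: values below a biomarker's limit of quantification are set to
    the limit and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise CohortValidationError(f"malformed CSV {path}: {exc}") from exc
    for col in ("subject", "visit"):
        if col not in df.columns:
            raise CohortValidationError(f"{path}: header lacks {col!r} column")
    cov_names = tuple(covariates) if covariates is not None else DEFAULT_COVARIATES
    covs = [c for c in df.columns if c in cov_names]
    bios = [c for c in df.columns if c not in covs and c not in ("subject", "visit")]
    n_loq = 0
    if config is not None:
        for b, loq in config.loq.items():
            if b in df.columns:
                below = df[b].notna() & (df[b] < loq)
                n_loq += int(below.sum())
                df.loc[below, b] = loq
    missing = int(df[bios].isna().sum().sum()) if bios else 0
    logger.info(
        "read %s: %d records, %d biomarkers, %d covariates, %d missing cells, "
        "%d LOQ substitutions",
        path, len(df), len(bios), len(covs), missing, n_loq,
    )
    return MeasurementTable(
        data=df,
        biomarkers=bios,
        covariates=covs,
        n_visits=int(n_visits or df["visit"].max()),
        loq_substitutions=n_loq,
    )


def write_cohort(table: MeasurementTable, path) -> None:
    table.data.to_csv(path, index=False)


def wide_to_long(
    df: pd.DataFrame,
    biomarker: str,
    visit_columns: Sequence[str],
    subject_column: str = "subject",
) -> pd.DataFrame:
    """Convert a wide clinical export (one column per visit) to tidy long form."""
    out = df.melt(
        id_vars=[subject_column],
        value_vars=list(visit_columns),
        var_name="visit",
        value_name=biomarker,
    )
    out["visit"] = [list(visit_columns).index(v) + 1 for v in out["visit"]]
    out = out.rename(columns={subject_column: "subject"})
    return out.sort_values(["subject", "visit"]).reset_index(drop=True)


_SLASH = "/"


def _fmt(x, nd=3):
    return _SLASH if x is None else f"{x:.{nd}f}"


def _row_record(row) -> dict:
    """JSON-faithful representation of one ReliabilityRow."""
    rcv = (
        {"symmetric": row.rcv.symmetric}
        if row.rcv.is_symmetric
        else {"up": row.rcv.up, "down": row.rcv.down}
    )
    rec = {
        "biomarker": row.biomarker,
        "n": row.n_subjects,
        "scale": row.scale,
        "icc": row.icc_crude.icc,
        "icc_ci_low": row.icc_crude.ci_low,
        "icc_ci_high": row.icc_crude.ci_high,
        "n_boot": row.icc_crude.n_boot,
        "cv_g": row.cv_g,
        "cv_t": row.cv_t,
        "ii": row.ii,
        "rcv": rcv,
        "n_beta_10": row.n_beta_10,
        "n_beta_20": row.n_beta_20,
        "category": row.category,
        "singular": row.singular,
        "excluded_subjects": [str(s) for s in row.excluded_subjects],
        "notes": row.notes,
    }
    if row.icc_adjusted is not None:
        rec["icc_adj"] = row.icc_adjusted.icc
        rec["icc_adj_ci_low"] = row.icc_adjusted.ci_low
        rec["icc_adj_ci_high"] = row.icc_adjusted.ci_high
    return rec


def write_reliability_report(rows, path) -> None:
    """Write the report as CSV plus a full-precision JSON sidecar.

    CSV columns mirror the published table layout (n, ICC [CI], CV_G,
    CV_T, II, RCV, n_beta columns, adjusted ICC [CI]); undefined cells are
    rendered as "/".
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    path = Path(path)
    recs = []
    for r in rows:
        if r.rcv.is_symmetric:
            rcv_pos = f"±{r.rcv.symmetric:.1f}"
            rcv_neg = _SLASH
        else:
            rcv_pos = f"+{r.rcv.up:.1f}"
            rcv_neg = f"{r.rcv.down:.1f}"
        rec = {
            "biomarker": r.biomarker,
            "n": r.n_subjects,
            "icc": f"{r.icc_crude.icc:.3f} [{r.icc_crude.ci_low:.3f}, {r.icc_crude.ci_high:.3f}]",
            "cv_g": _fmt(r.cv_g),
            "cv_t": _fmt(r.cv_t),
            "ii": _fmt(r.ii),
            "rcv_pos": rcv_pos,
            "rcv_neg": rcv_neg,
            "n_beta_10": _SLASH if r.n_beta_10 is None else str(r.n_beta_10),
            "n_beta_20": _SLASH if r.n_beta_20 is None else str(r.n_beta_20),
            "category": r.category,
        }
        if r.icc_adjusted is not None:
            a = r.icc_adjusted
            rec["icc_adj"] = f"{a.icc:.3f} [{a.ci_low:.3f}, {a.ci_high:.3f}]"
        else:
            rec["icc_adj"] = _SLASH
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump([_row_record(r) for r in rows], fh, indent=1)


def read_reliability_report(path) -> list[dict]:
    """Read back the JSON sidecar written by :func:`write_reliability_report`."""
    sidecar = Path(path).with_suffix(".json")
    with open(sidecar) as fh:
        return json.load(fh)
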