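"""End-to-end orchestration: screen -> transform -> fit -> metrics -> report.

Per biomarker the pipeline (i) decides the analysis scale (configured
override or Shapiro-Wilk recommendation), (ii) screens subjects with
Cochran's C on within-subject variances and Reed's criterion on subject
means, (iii) fits the crude one-way REML model with a subject-bootstrap
ICC CI, (iv) fits the covariate-adjusted model, and (v) derives the
biological-variation metrics (CVs, II, RCV, n_beta, category).  Two
sensitivity modes repeat the analysis after iterative residual exclusion
or after dropping subjects with predefined conditions.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import AnalysisConfig, MeasurementTable, DEFAULT_LOG_TRANSFORM
from .reliability_metrics import ReliabilityRow, build_reliability_row
from .screening import recommend_transform, screen_biomarker
from .variance_models import (
    ICCResult,
    bootstrap_icc_ci,
    fit_mixed_covariates,
    fit_oneway_random,
    icc_from_components,
    iterative_residual_exclusion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivitySpec",
    "run_reliability_analysis",
    "run_sensitivity",
    "analyze_biomarker",
    "longitudinal_shift_tests",
    "baseline_correlation_matrix",
]

#: Subgroup-exclusion flag columns (binary covariates) recognized by the
#: subgroup sensitivity mode.
SUBGROUP_FLAGS = (
    "contraceptive",
    "analgesic",
    "vaccination",
    "abnormal_cycle",
    "health_problem",
)


@dataclass
class SensitivitySpec:
    mode: str  # "residual" | "subgroup"
    residual_cutoff: float = 2.0
    exclusion_flags: tuple[str, ...] = SUBGROUP_FLAGS
    hscrp_column: str = "hs_crp"
    hscrp_threshold: float = 95.0  # nmol/L

    def __post_init__(self) -> None:
        if self.mode not in ("residual", "subgroup"):
            raise ValueError(f"unknown sensitivity mode {self.mode!r}")
        if self.mode == "subgroup" and not self.exclusion_flags:
            raise ValueError("subgroup mode needs at least one exclusion flag")


def _biomarker_seed(seed: int, biomarker: str) -> int:
    return (seed * 1000003 + zlib.crc32(biomarker.encode())) % (2**31)


def _decide_scale(table, biomarker: str, config: AnalysisConfig) -> str:
    if biomarker in config.transform:
        return "log" if config.transform[biomarker] else "raw"
    if biomarker in DEFAULT_LOG_TRANSFORM:
        return "log" if DEFAULT_LOG_TRANSFORM[biomarker] else "raw"
    dec = recommend_transform(table, biomarker, alpha=0.05)
    return "log" if dec.log else "raw"


def analyze_biomarker(
    table: MeasurementTable,
    biomarker: str,
    config: AnalysisConfig,
    *,
    adjusted: bool = True,
    pre_excluded: Optional[list] = None,
) -> ReliabilityRow:
    """Screen, fit and summarize a single biomarker."""
    scale = _decide_scale(table, biomarker, config)
    clean, screen_report = screen_biomarker(
        table,
        biomarker,
        config.cochran_alpha,
        scale=scale,
        bonferroni=config.cochran_bonferroni,
        iterative=config.iterative_screen,
    )
    if screen_report.excluded_subjects:
        logger.info(
            "%s: screening excluded %s", biomarker, screen_report.subject_ids
        )
    seed = _biomarker_seed(config.seed, biomarker)
    fit = fit_oneway_random(clean, biomarker, scale)
    try:
        icc_crude = bootstrap_icc_ci(
            clean, biomarker, scale=scale, B=config.n_boot, seed=seed,
            method=config.bootstrap_method,
        )
    except RuntimeError:
        icc_crude = ICCResult(
            icc=icc_from_components(fit.components),
            ci_low=0.0, ci_high=1.0, n_boot=0,
        )
    icc_adj = None
    if adjusted:
        covs = config.covariates_for(biomarker, clean.data.columns)
        if covs:
            try:
                fit_mixed_covariates(clean, biomarker, covs, scale)  # fail fast
                icc_adj = bootstrap_icc_ci(
                    clean, biomarker, covariates=covs, scale=scale,
                    B=config.n_boot, seed=seed + 1,
                    method=config.bootstrap_method,
                )
            except (ValueError, RuntimeError) as exc:
                logger.warning("%s: adjusted model failed (%s)", biomarker, exc)
    notes = ""
    if fit.components.singular:
        notes = "singular fit"
    excluded = list(pre_excluded or []) + screen_report.subject_ids
    return build_reliability_row(
        biomarker,
        fit,
        icc_crude,
        z=config.z,
        attenuation_levels=config.attenuation_levels,
        icc_adjusted=icc_adj,
        excluded_subjects=excluded,
        notes=notes,
    )


def run_reliability_analysis(
    table: MeasurementTable, config: AnalysisConfig
) -> list[ReliabilityRow]:
    """Full crude + adjusted analysis for every biomarker in the table.

    A biomarker whose model cannot be fitted (fewer than 3 usable
    subjects, say) yields a flagged placeholder row rather than aborting
    the run.  Deterministic given (table, config, config.seed).
    """
    rows = []
    for biomarker in table.biomarkers:
        try:
            rows.append(analyze_biomarker(table, biomarker, config))
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: analysis failed (%s)", biomarker, exc)
            rows.append(_failed_row(biomarker, str(exc)))
    return rows


def _failed_row(biomarker: str, reason: str) -> ReliabilityRow:
    from .reliability_metrics import RCV

    return ReliabilityRow(
        biomarker=biomarker,
        n_subjects=0,
        icc_crude=ICCResult(icc=0.0, ci_low=0.0, ci_high=1.0, n_boot=0),
        cv_g=0.0,
        cv_t=0.0,
        ii=None,
        rcv=RCV(symmetric=0.0),
        n_beta_10=None,
        n_beta_20=None,
        category="poor",
        notes=f"analysis failed: {reason}",
    )


def run_sensitivity(
    table: MeasurementTable,
    config: AnalysisConfig,
    spec: SensitivitySpec,
) -> list[ReliabilityRow]:
    """Sensitivity re-analysis.

    * ``residual`` mode: after screening, subjects with any standardized
      conditional residual above the cutoff are excluded model-wise and
      iteratively; crude and adjusted metrics are recomputed on the
      remaining subjects.
    * ``subgroup`` mode: subjects with any set exclusion flag (or an
      hs-CRP value at/above the threshold at any visit) are dropped,
      screening and residual inspection are repeated, and crude-only
      metrics are reported (no adjusted ICC at the reduced sample size).
    """
    if spec.mode == "residual":
        return _run_residual_mode(table, config, spec)
    return _run_subgroup_mode(table, config, spec)


def _run_residual_mode(table, config, spec) -> list[ReliabilityRow]:
    rows = []
    for biomarker in table.biomarkers:
        try:
            scale = _decide_scale(table, biomarker, config)
            clean, screen_rep = screen_biomarker(
                table, biomarker, config.cochran_alpha, scale=scale,
                bonferroni=config.cochran_bonferroni,
                iterative=config.iterative_screen,
            )
            fit, resid_rep = iterative_residual_exclusion(
                clean, biomarker, scale=scale, cutoff=spec.residual_cutoff
            )
            kept = clean.drop_subjects(resid_rep.subject_ids)
            row = analyze_biomarker(
                kept, biomarker, config,
                pre_excluded=screen_rep.subject_ids + resid_rep.subject_ids,
            )
            rows.append(row)
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: residual sensitivity failed (%s)", biomarker, exc)
            rows.append(_failed_row(biomarker, str(exc)))
    return rows


def _flagged_subjects(table, spec: SensitivitySpec) -> list:
    df = table.data
    flagged = set()
    for flag in spec.exclusion_flags:
        if flag in df.columns:
            hit = df.loc[df[flag].fillna(0) > 0, "subject"]
            flagged.update(hit)
    if spec.hscrp_column in df.columns:
        hit = df.loc[df[spec.hscrp_column] >= spec.hscrp_threshold, "subject"]
        flagged.update(hit)
    return sorted(flagged)


def _run_subgroup_mode(table, config, spec) -> list[ReliabilityRow]:
    flagged = _flagged_subjects(table, spec)
    reduced = table.drop_subjects(flagged)
    if reduced.n_subjects < 3:
        raise ValueError(
            f"subgroup exclusion on flags {spec.exclusion_flags} leaves "
            f"{reduced.n_subjects} subjects"
        )
    logger.info("subgroup mode: excluded %d subjects", len(flagged))
    rows = []
    for biomarker in reduced.biomarkers:
        try:
            scale = _decide_scale(reduced, biomarker, config)
            clean, screen_rep = screen_biomarker(
                reduced, biomarker, config.cochran_alpha, scale=scale,
                bonferroni=config.cochran_bonferroni,
                iterative=config.iterative_screen,
            )
            _, resid_rep = iterative_residual_exclusion(
                clean, biomarker, scale=scale, cutoff=spec.residual_cutoff
            )
            kept = clean.drop_subjects(resid_rep.subject_ids)
            row = analyze_biomarker(
                kept, biomarker, config, adjusted=False,
                pre_excluded=list(flagged) + screen_rep.subject_ids
                + resid_rep.subject_ids,
            )
            rows.append(row)
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: subgroup sensitivity failed (%s)", biomarker, exc)
            rows.append(_failed_row(biomarker, str(exc)))
    return rows


def _compact_letters(k: int, significant_pairs: set[tuple[int, int]]) -> list[str]:
    """Compact letter display: groups share a letter iff no significant
    difference separates them (insert-and-absorb algorithm)."""
    sets: list[set[int]] = [set(range(k))]
    for (i, j) in significant_pairs:
        new_sets = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    letters = [""] * k
    for idx, s in enumerate(sets):
        for g in sorted(s):
            letters[g] += chr(ord("a") + idx)
    return letters


def longitudinal_shift_tests(
    table: MeasurementTable, biomarker: str, alpha: float = 0.05
) -> dict:
    """Friedman test across visits; Bonferroni-adjusted Wilcoxon pairs if
    significant; visits labelled with shared/distinct homogeneity letters.

    Only subjects with a complete set of visits enter the test.
    """
    df = table.data.pivot(index="subject", columns="visit", values=biomarker)
    complete = df.dropna()
    if len(complete) < 3:
        raise ValueError(f"fewer than 3 complete subjects for {biomarker!r}")
    cols = [complete[v].to_numpy() for v in sorted(complete.columns)]
    k = len(cols)
    if np.ptp(np.concatenate(cols)) == 0:
        return {
            "statistic": 0.0, "p_overall": 1.0, "pairwise": {},
            "letters": ["a"] * k, "n_complete": len(complete),
        }
    stat, p_overall = stats.friedmanchisquare(*cols)
    pairwise: dict[tuple[int, int], float] = {}
    sig_pairs: set[tuple[int, int]] = set()
    if p_overall < alpha:
        pairs = list(itertools.combinations(range(k), 2))
        for (i, j) in pairs:
            diff = cols[i] - cols[j]
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(cols[i], cols[j]).pvalue)
            p_adj = min(1.0, p * len(pairs))
            pairwise[(i + 1, j + 1)] = p_adj
            if p_adj < alpha:
                sig_pairs.add((i, j))
    letters = _compact_letters(k, sig_pairs)
    return {
        "statistic": float(stat),
        "p_overall": float(p_overall),
        "pairwise": pairwise,
        "letters": letters,
        "n_complete": len(complete),
    }


def baseline_correlation_matrix(
    table: MeasurementTable, visit: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix among biomarkers at one visit.

    Returns (rho, p) DataFrames; constant columns yield NaN entries.
    """
    df = table.data[table.data["visit"] == visit]
    if df.empty:
        raise ValueError(f"no records at visit {visit}")
    names = table.biomarkers
    k = len(names)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = df[names[i]], df[names[j]]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x[ok], y[ok])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(rho, index=names, columns=names),
        pd.DataFrame(pmat, index=names, columns=names),
    )
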