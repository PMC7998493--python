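"""REML variance-component estimation for repeated biomarker measurements.

The working model is a random-intercept linear mixed model

    y_ij = x_ij' beta + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_w^2),

for subject i observed at visits j.  The crude ("one-way") model has an
intercept only; the adjusted model carries the configured covariates as
fixed effects.  Estimation is restricted maximum likelihood through the
profile over the variance ratio lambda = sigma_b^2 / sigma_w^2: for a
given lambda the GLS fixed effects and the residual variance have closed
forms, so a single bounded 1-D search on log(lambda) suffices.  The
between-subject variance is truncated at the zero boundary and the fit is
flagged *singular* there, matching the convention of mixed-model software.

The ICC is sigma_b^2 / (sigma_b^2 + sigma_w^2).  Confidence intervals are
obtained by resampling subjects with replacement (all of a subject's
visits travel together), refitting, and taking percentile bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "VarianceComponents",
    "MixedModelFit",
    "ICCResult",
    "fit_oneway_random",
    "fit_mixed_covariates",
    "icc_from_components",
    "bootstrap_icc_ci",
    "iterative_residual_exclusion",
    "reml_neg2loglik",
]

_LOG_LAMBDA_BOUNDS = (-30.0, 30.0)
_XATOL = 1e-10


@dataclass
class VarianceComponents:
    """Between- and within-subject variances on the analysis scale."""

    sigma2_between: float
    sigma2_within: float
    grand_mean: float
    scale: str = "raw"  # "raw" | "log"
    singular: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")
        if self.scale not in ("raw", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")


@dataclass
class MixedModelFit:
    components: VarianceComponents
    fixed_effects: dict[str, float]
    residuals: pd.DataFrame  # subject, visit, resid_std (conditional)
    n_subjects_used: int
    biomarker: str = ""
    dropped_subjects: list = field(default_factory=list)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_boot: int
    adjusted: bool = False

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def reml_neg2loglik(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    counts: np.ndarray,
) -> tuple[float, np.ndarray, float]:
    """Profile -2 restricted log-likelihood (up to an additive constant).

    For V = I + lam * J (block-diagonal per subject) the GLS estimate of
    beta and the REML residual variance are closed-form, giving

        -2 l_R(lam) = log|V| + log|X'V^-1 X| + (n - p) log sigma_w^2(lam).

    Returns (objective, beta, sigma2_w).  Exposed so that grid-search
    oracles can interrogate the same surface the optimizer sees.
    """
    n, p = X.shape
    G = len(counts)
    w = lam / (1.0 + lam * counts)  # per-group Sherman-Morrison weight
    Sy = np.bincount(gidx, weights=y, minlength=G)
    SX = np.empty((G, p))
    for j in range(p):
        SX[:, j] = np.bincount(gidx, weights=X[:, j], minlength=G)
    XtVX = X.T @ X - (SX * w[:, None]).T @ SX
    XtVy = X.T @ y - SX.T @ (w * Sy)
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    Sr = Sy - SX @ beta
    rtVr = r @ r - float(w @ (Sr * Sr))
    sigma2 = max(rtVr / (n - p), 1e-300)
    logdetV = float(np.sum(np.log1p(lam * counts)))
    _, logdetX = np.linalg.slogdet(XtVX)
    obj = logdetV + logdetX + (n - p) * math.log(sigma2)
    return obj, beta, sigma2


def _reml_score(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    counts: np.ndarray,
) -> float:
    """d/d(lambda) of the profile -2 restricted log-likelihood.

    Analytic form (envelope theorem removes the beta(lambda) terms):

        sum_g n_g/(1+lam n_g)
        - tr[(X'V^-1 X)^-1 sum_g SX_g SX_g'/(1+lam n_g)^2]
        - (n-p) * sum_g Sr_g^2/(1+lam n_g)^2 / (r'V^-1 r)

    Used to polish the Brent optimum to machine precision, where the
    objective itself is too flat to resolve.
    """
    n, p = X.shape
    G = len(counts)
    denom = 1.0 + lam * counts
    w = lam / denom
    Sy = np.bincount(gidx, weights=y, minlength=G)
    SX = np.empty((G, p))
    for j in range(p):
        SX[:, j] = np.bincount(gidx, weights=X[:, j], minlength=G)
    XtVX = X.T @ X - (SX * w[:, None]).T @ SX
    XtVy = X.T @ y - SX.T @ (w * Sy)
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    Sr = Sy - SX @ beta
    rtVr = r @ r - float(w @ (Sr * Sr))
    w2 = 1.0 / (denom * denom)
    B = (SX * w2[:, None]).T @ SX
    term_logdetV = float(np.sum(counts / denom))
    term_logdetX = float(np.trace(np.linalg.solve(XtVX, B)))
    term_sigma = (n - p) * float(w2 @ (Sr * Sr)) / rtVr
    return term_logdetV - term_logdetX - term_sigma


def _fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    *,
    scale: str,
    colnames: Sequence[str],
    xatol: float = _XATOL,
) -> tuple[VarianceComponents, np.ndarray, np.ndarray]:
    """Core REML fit on prepared arrays.

    Returns (components, beta, standardized conditional residuals).
    """
    counts = np.bincount(gidx, minlength=n_groups).astype(float)
    n, p = X.shape

    # Degenerate data guards: no variation at all, or no within-subject
    # variation (each subject's repeats identical).
    group_mean = np.bincount(gidx, weights=y, minlength=n_groups) / counts
    ssw = float(np.sum((y - group_mean[gidx]) ** 2))
    if np.ptp(y) == 0.0:
        vc = VarianceComponents(0.0, 0.0, float(y[0]), scale, singular=True)
        beta = np.zeros(p)
        beta[0] = float(y[0])
        return vc, beta, np.zeros(n)

    if ssw == 0.0 and p == 1:
        # Pure between-subject variation: sigma_w = 0, ICC -> 1.
        gm = float(np.mean(group_mean))
        s_b2 = float(np.var(group_mean, ddof=1))
        vc = VarianceComponents(s_b2, 0.0, gm, scale, singular=False)
        return vc, np.array([gm]), np.zeros(n)

    def obj(t: float) -> float:
        return reml_neg2loglik(math.exp(t), y, X, gidx, counts)[0]

    res = minimize_scalar(
        obj,
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": max(xatol, 1e-8)},
    )
    t_opt = float(res.x)
    # Polish with the analytic score: the objective is too flat near the
    # optimum for a derivative-free search to beat ~1e-8 relative error.
    if xatol < 1e-8:
        lo, hi = t_opt - 0.5, t_opt + 0.5
        s_lo = _reml_score(math.exp(lo), y, X, gidx, counts)
        s_hi = _reml_score(math.exp(hi), y, X, gidx, counts)
        if s_lo < 0 < s_hi:
            t_opt = brentq(
                lambda t: _reml_score(math.exp(t), y, X, gidx, counts),
                lo, hi, xtol=1e-14,
            )
    obj0, beta0, sigma2_0 = reml_neg2loglik(0.0, y, X, gidx, counts)
    if obj0 <= obj(t_opt) + 1e-12:
        lam, beta, sigma2_w = 0.0, beta0, sigma2_0
        singular = True
    else:
        lam = math.exp(t_opt)
        _, beta, sigma2_w = reml_neg2loglik(lam, y, X, gidx, counts)
        singular = False
    sigma2_b = lam * sigma2_w

    # Standardized conditional residuals: shrink the per-subject mean
    # marginal residual into an empirical BLUP, subtract, scale by sigma_w.
    r = y - X @ beta
    if sigma2_w > 0:
        shrink = lam * counts / (1.0 + lam * counts)
        blup = shrink * (np.bincount(gidx, weights=r, minlength=n_groups) / counts)
        resid_std = (r - blup[gidx]) / math.sqrt(sigma2_w)
    else:
        resid_std = np.zeros(n)

    grand_mean = float(beta[0]) if p >= 1 else float(np.mean(y))
    vc = VarianceComponents(sigma2_b, sigma2_w, grand_mean, scale, singular=singular)
    return vc, beta, resid_std


def _prepare_arrays(
    table,
    biomarker: str,
    covariates: Optional[Sequence[str]],
    scale: str,
):
    """Extract (y, X, gidx, subjects, visits, dropped, colnames) from a table.

    Records with a missing biomarker value are dropped individually;
    subjects missing any covariate at any visit are dropped listwise.
    Constant covariates carry no information beyond the intercept and are
    silently excluded from the design.
    """
    df = table.data
    dropped: list = []
    keep = df[biomarker].notna()
    use_covs: list[str] = []
    if covariates:
        for c in covariates:
            if c not in df.columns:
                raise KeyError(f"covariate column {c!r} not in table")
        bad = df.loc[keep, covariates].isna().any(axis=1)
        bad_subjects = set(df.loc[keep].loc[bad, "subject"])
        if bad_subjects:
            dropped = sorted(bad_subjects)
            keep &= ~df["subject"].isin(bad_subjects)
        sub = df.loc[keep]
        use_covs = [c for c in covariates if sub[c].nunique() > 1]
    sub = df.loc[keep]
    if sub.empty:
        raise ValueError(f"no usable observations for {biomarker!r}")
    y = sub[biomarker].to_numpy(dtype=float)
    if scale == "log":
        if np.any(y <= 0):
            raise ValueError(f"log scale requires positive values for {biomarker!r}")
        y = np.log(y)
    subjects, gidx = np.unique(sub["subject"].to_numpy(), return_inverse=True)
    if len(subjects) < 3:
        raise ValueError(
            f"need at least 3 subjects with data for {biomarker!r}, "
            f"got {len(subjects)}"
        )
    counts = np.bincount(gidx)
    if counts.max() < 2:
        raise ValueError(
            "within-subject variance is unidentifiable: every subject has a "
            "single visit"
        )
    n = len(y)
    X = np.ones((n, 1 + len(use_covs)))
    colnames = ["intercept"]
    for j, c in enumerate(use_covs, start=1):
        col = sub[c].to_numpy(dtype=float)
        X[:, j] = col - col.mean()  # center: conditioning only, slopes unchanged
        colnames.append(c)
    if len(use_covs) >= 1:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            collinear = _find_collinear(X, colnames)
            raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return y, X, gidx, subjects, sub["visit"].to_numpy(), dropped, colnames


def _find_collinear(X: np.ndarray, colnames: Sequence[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    out = []
    for j in range(1, X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(colnames[j])
    return out


def _build_fit(
    vc: VarianceComponents,
    beta: np.ndarray,
    resid_std: np.ndarray,
    subjects: np.ndarray,
    gidx: np.ndarray,
    visits: np.ndarray,
    colnames: Sequence[str],
    biomarker: str,
    dropped: list,
) -> MixedModelFit:
    residuals = pd.DataFrame(
        {"subject": subjects[gidx], "visit": visits, "resid_std": resid_std}
    )
    return MixedModelFit(
        components=vc,
        fixed_effects=dict(zip(colnames, map(float, beta))),
        residuals=residuals,
        n_subjects_used=len(subjects),
        biomarker=biomarker,
        dropped_subjects=dropped,
    )


def fit_oneway_random(table, biomarker: str, scale: str = "raw") -> MixedModelFit:
    """Crude one-way random-effects model: intercept plus subject intercepts.

    REML estimates of (mu, sigma_b^2, sigma_w^2); for balanced data these
    coincide with the ANOVA method-of-moments values sigma_w^2 = MSW and
    sigma_b^2 = max(0, (MSB - MSW)/k).
    """
    y, X, gidx, subjects, visits, dropped, colnames = _prepare_arrays(
        table, biomarker, None, scale
    )
    vc, beta, resid = _fit_random_intercept(
        y, X, gidx, len(subjects), scale=scale, colnames=colnames
    )
    return _build_fit(vc, beta, resid, subjects, gidx, visits, colnames, biomarker, dropped)


def fit_mixed_covariates(
    table,
    biomarker: str,
    covariates: Sequence[str],
    scale: str = "raw",
) -> MixedModelFit:
    """Covariate-adjusted random-intercept model.

    Covariates enter as fixed effects (mean-centered for conditioning;
    slopes are unaffected).  Subjects missing any covariate at any visit
    are dropped listwise and recorded in ``dropped_subjects``.
    """
    y, X, gidx, subjects, visits, dropped, colnames = _prepare_arrays(
        table, biomarker, covariates, scale
    )
    vc, beta, resid = _fit_random_intercept(
        y, X, gidx, len(subjects), scale=scale, colnames=colnames
    )
    return _build_fit(vc, beta, resid, subjects, gidx, visits, colnames, biomarker, dropped)


def icc_from_components(vc: VarianceComponents) -> float:
    """ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2); 0 for singular fits."""
    total = vc.sigma2_between + vc.sigma2_within
    if total == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    if vc.singular and vc.sigma2_between == 0:
        return 0.0
    return vc.sigma2_between / total


def bootstrap_icc_ci(
    table,
    biomarker: str,
    *,
    covariates: Optional[Sequence[str]] = None,
    scale: str = "raw",
    B: int = 2000,
    seed: int = 0,
    method: str = "percentile",
    ci_level: float = 0.95,
) -> ICCResult:
    """Subject-level bootstrap CI for the ICC.

    Subjects are resampled with replacement and refitted B times; with
    ``method="percentile"`` the 2.5/97.5 percentile bounds are reported
    (``"normal"`` gives the normal-approximation interval).  Bounds are
    clipped to [0, 1].  Deterministic given ``seed``.  Raises if more than
    half the refits fail.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if method not in ("percentile", "normal"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    y, X, gidx, subjects, _, _, colnames = _prepare_arrays(
        table, biomarker, covariates, scale
    )
    G = len(subjects)
    point_vc, _, _ = _fit_random_intercept(
        y, X, gidx, G, scale=scale, colnames=colnames
    )
    point = icc_from_components(point_vc)

    # Row indices per subject, so a resampled cohort is a concatenation.
    order = np.argsort(gidx, kind="stable")
    bounds = np.searchsorted(gidx[order], np.arange(G + 1))
    rows_by_subject = [order[bounds[g]: bounds[g + 1]] for g in range(G)]

    rng = np.random.default_rng(seed)
    iccs = np.empty(B)
    failures = 0
    for b in range(B):
        draw = rng.integers(0, G, size=G)
        rows = np.concatenate([rows_by_subject[g] for g in draw])
        new_gidx = np.repeat(np.arange(G), [len(rows_by_subject[g]) for g in draw])
        try:
            vc, _, _ = _fit_random_intercept(
                y[rows], X[rows], new_gidx, G, scale=scale,
                colnames=colnames, xatol=1e-8,
            )
            iccs[b] = icc_from_components(vc)
        except (ValueError, np.linalg.LinAlgError):
            iccs[b] = np.nan
            failures += 1
    if failures > B / 2:
        raise RuntimeError(
            f"bootstrap failed in {failures}/{B} replicates for {biomarker!r}"
        )
    good = iccs[~np.isnan(iccs)]
    tail = (1.0 - ci_level) / 2.0
    if method == "percentile":
        lo, hi = np.percentile(good, [100 * tail, 100 * (1 - tail)])
    else:
        from scipy import stats as _st

        z = _st.norm.ppf(1 - tail)
        sd = float(np.std(good, ddof=1))
        lo, hi = point - z * sd, point + z * sd
    return ICCResult(
        icc=point,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        n_boot=B,
        adjusted=bool(covariates),
    )


def iterative_residual_exclusion(
    table,
    biomarker: str,
    *,
    covariates: Optional[Sequence[str]] = None,
    scale: str = "raw",
    cutoff: float = 2.0,
):
    """Drop subjects with any |standardized conditional residual| > cutoff.

    Refits after each exclusion round until no residual exceeds the cutoff
    or fewer than 3 subjects remain (which raises).  Returns
    ``(final_fit, OutlierReport)``; the report lists one entry per excluded
    subject with the offending residual magnitude.
    """
    from .screening import Exclusion, OutlierReport

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    current = table
    exclusions: list[Exclusion] = []
    iterations = 0
    while True:
        if covariates:
            fit = fit_mixed_covariates(current, biomarker, covariates, scale)
        else:
            fit = fit_oneway_random(current, biomarker, scale)
        if not math.isfinite(cutoff):
            break
        res = fit.residuals
        worst = res.groupby("subject")["resid_std"].agg(lambda s: s.abs().max())
        offenders = worst[worst > cutoff]
        if offenders.empty:
            break
        iterations += 1
        for subj, stat in offenders.items():
            exclusions.append(
                Exclusion(subject_id=subj, rule="residual",
                          statistic=float(stat), threshold=cutoff)
            )
        remaining = set(res["subject"]) - set(offenders.index)
        if len(remaining) < 3:
            raise RuntimeError(
                f"residual exclusion exhausted subjects for {biomarker!r}; "
                f"trace: {[e.subject_id for e in exclusions]}"
            )
        current = current.subset_subjects(sorted(remaining))
    return fit, OutlierReport(excluded_subjects=exclusions, iterations=iterations)
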