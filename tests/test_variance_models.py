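"""REML variance components, ICC, bootstrap CI and residual exclusion."""

import math

import numpy as np
import pandas as pd
import pytest

from biovariation import (
    BiomarkerSpec,
    ICCResult,
    MeasurementTable,
    OutlierInjection,
    SyntheticSpec,
    VarianceComponents,
    bootstrap_icc_ci,
    fit_mixed_covariates,
    fit_oneway_random,
    generate_cohort,
    icc_from_components,
    inject_outliers,
    iterative_residual_exclusion,
)
from biovariation.variance_models import reml_neg2loglik
from conftest import single_biomarker_spec


def anova_components(table, biomarker, scale):
    """Independent balanced-data oracle: one-way ANOVA method of moments."""
    wide = table.data.pivot(index="subject", columns="visit", values=biomarker)
    y = wide.to_numpy(dtype=float)
    if scale == "log":
        y = np.log(y)
    k = y.shape[1]
    msb = k * np.var(y.mean(axis=1), ddof=1)
    msw = float(np.mean(np.var(y, axis=1, ddof=1)))
    return max(0.0, (msb - msw) / k), msw


class TestOnewayREML:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_balanced_equals_anova_closed_form(self, seed):
        spec = single_biomarker_spec(0.6, seed=seed)
        table = generate_cohort(spec)
        fit = fit_oneway_random(table, "marker", "log")
        s_b2, s_w2 = anova_components(table, "marker", "log")
        assert fit.components.sigma2_between == pytest.approx(s_b2, rel=1e-8)
        assert fit.components.sigma2_within == pytest.approx(s_w2, rel=1e-8)

    def test_balanced_negative_moment_truncates_to_singular(self):
        # low ICC + few subjects: MSB < MSW happens; REML must hit the boundary
        found = False
        for seed in range(40):
            spec = single_biomarker_spec(0.02, n_subjects=8, seed=seed)
            table = generate_cohort(spec)
            wide = table.data.pivot(index="subject", columns="visit", values="marker")
            y = np.log(wide.to_numpy())
            msb = 3 * np.var(y.mean(axis=1), ddof=1)
            msw = np.mean(np.var(y, axis=1, ddof=1))
            if msb < msw:
                fit = fit_oneway_random(table, "marker", "log")
                assert fit.components.singular
                assert fit.components.sigma2_between == 0.0
                assert icc_from_components(fit.components) == 0.0
                found = True
                break
        assert found, "no negative-moment draw encountered"

    def test_profile_optimum_beats_grid(self):
        """REML objective at the optimum is no worse than anywhere on a
        fine lambda grid, evaluated through an independent closed form
        for balanced one-way data."""
        spec = single_biomarker_spec(0.6, n_subjects=6, seed=9)
        table = generate_cohort(spec)
        fit = fit_oneway_random(table, "marker", "log")
        wide = table.data.pivot(index="subject", columns="visit", values="marker")
        y = np.log(wide.to_numpy())
        G, k = y.shape
        n = G * k
        ssb = k * np.sum((y.mean(axis=1) - y.mean()) ** 2)
        ssw = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2)
        lam_grid = np.arange(0.0, 100.0, 1e-4)
        # closed-form profile -2 log REML for balanced one-way data
        rtvr = ssw + ssb / (1 + k * lam_grid)
        sigma2 = rtvr / (n - 1)
        obj_grid = (
            G * np.log1p(k * lam_grid)
            + np.log(G * k / (1 + k * lam_grid))
            + (n - 1) * np.log(sigma2)
        )
        lam_hat = fit.components.sigma2_between / fit.components.sigma2_within
        rtvr_hat = ssw + ssb / (1 + k * lam_hat)
        obj_hat = (
            G * math.log1p(k * lam_hat)
            + math.log(G * k / (1 + k * lam_hat))
            + (n - 1) * math.log(rtvr_hat / (n - 1))
        )
        assert obj_hat <= obj_grid.min() + 1e-9

    def test_unbalanced_matches_statsmodels(self):
        import statsmodels.formula.api as smf

        spec = single_biomarker_spec(0.6, seed=13)
        table = generate_cohort(spec)
        df = table.data.drop(index=[0, 4, 10, 50]).reset_index(drop=True)
        table = MeasurementTable(
            data=df, biomarkers=["marker"], covariates=[], n_visits=3
        )
        fit = fit_oneway_random(table, "marker", "log")
        d = df.copy()
        d["ly"] = np.log(d["marker"])
        sm_fit = smf.mixedlm("ly ~ 1", d, groups=d["subject"]).fit(reml=True)
        assert fit.components.sigma2_between == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-4
        )
        assert fit.components.sigma2_within == pytest.approx(
            float(sm_fit.scale), rel=1e-4
        )

    def test_record_order_irrelevant(self):
        spec = single_biomarker_spec(0.6, seed=21)
        table = generate_cohort(spec)
        fit1 = fit_oneway_random(table, "marker", "log")
        shuffled = MeasurementTable(
            data=table.data.sample(frac=1, random_state=0).reset_index(drop=True),
            biomarkers=["marker"],
            covariates=table.covariates,
            n_visits=3,
        )
        fit2 = fit_oneway_random(shuffled, "marker", "log")
        assert fit1.components.sigma2_between == pytest.approx(
            fit2.components.sigma2_between, rel=1e-12
        )

    def test_zero_within_variance_gives_icc_one(self):
        df = pd.DataFrame(
            {
                "subject": np.repeat(list("ABCDE"), 3),
                "visit": np.tile([1, 2, 3], 5),
                "marker": np.repeat([3.0, 5.0, 7.0, 11.0, 13.0], 3),
            }
        )
        table = MeasurementTable(data=df, biomarkers=["marker"], n_visits=3)
        fit = fit_oneway_random(table, "marker")
        assert icc_from_components(fit.components) == 1.0

    def test_all_identical_is_singular_icc_zero(self):
        df = pd.DataFrame(
            {
                "subject": np.repeat(list("ABCDE"), 3),
                "visit": np.tile([1, 2, 3], 5),
                "marker": 4.2,
            }
        )
        table = MeasurementTable(data=df, biomarkers=["marker"], n_visits=3)
        fit = fit_oneway_random(table, "marker")
        assert fit.components.singular
        with pytest.raises(ValueError):
            icc_from_components(fit.components)

    def test_single_visit_everywhere_unidentifiable(self):
        df = pd.DataFrame(
            {
                "subject": list("ABCDE"),
                "visit": [1] * 5,
                "marker": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        table = MeasurementTable(data=df, biomarkers=["marker"], n_visits=3)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_oneway_random(table, "marker")

    def test_recovery_across_icc_range(self):
        """Mean estimated crude ICC over 500 synthetic 44x3 cohorts is
        within +-0.05 of the truth (log-scale random-intercept model)."""
        for truth in (0.3, 0.5, 0.7, 0.875):
            est = []
            for i in range(125):
                spec = single_biomarker_spec(truth, seed=50_000 + i)
                fit = fit_oneway_random(generate_cohort(spec), "marker", "log")
                est.append(icc_from_components(fit.components))
            assert abs(np.mean(est) - truth) < 0.05, truth


class TestAdjustedModel:
    def test_constant_covariate_equals_crude(self, toy_table):
        toy_table.data["flat"] = 1.7
        toy_table.covariates.append("flat")
        crude = fit_oneway_random(toy_table, "marker")
        adj = fit_mixed_covariates(toy_table, "marker", ["flat"])
        assert adj.components.sigma2_between == pytest.approx(
            crude.components.sigma2_between, abs=1e-8
        )
        assert adj.components.sigma2_within == pytest.approx(
            crude.components.sigma2_within, abs=1e-8
        )

    def test_duplicated_covariate_names_collinear(self, toy_table):
        toy_table.data["bmi2"] = toy_table.data["bmi"]
        with pytest.raises(ValueError, match="collinear"):
            fit_mixed_covariates(toy_table, "marker", ["bmi", "bmi2"])

    def test_covariate_grid_oracle(self):
        """4-subject toy fit matches a brute-force dense-matrix profile
        optimizer (independent GLS route) within 1e-5."""
        rng = np.random.default_rng(3)
        G, k = 4, 3
        x = rng.normal(size=G * k)
        b = np.repeat(rng.normal(0, 1.0, G), k)
        y = 2.0 + 0.8 * x + b + rng.normal(0, 0.6, G * k)
        df = pd.DataFrame(
            {
                "subject": np.repeat([f"P{i}" for i in range(G)], k),
                "visit": np.tile([1, 2, 3], G),
                "marker": y - y.min() + 1.0,
                "x": x,
            }
        )
        table = MeasurementTable(
            data=df, biomarkers=["marker"], covariates=["x"], n_visits=3
        )
        fit = fit_mixed_covariates(table, "marker", ["x"])

        yy = df["marker"].to_numpy()
        X = np.column_stack([np.ones(G * k), x - x.mean()])
        Z = np.kron(np.eye(G), np.ones((k, 1)))

        def dense_profile(lam):
            V = np.eye(G * k) + lam * Z @ Z.T
            Vi = np.linalg.inv(V)
            A = X.T @ Vi @ X
            beta = np.linalg.solve(A, X.T @ Vi @ yy)
            r = yy - X @ beta
            s2 = r @ Vi @ r / (G * k - 2)
            obj = (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(A)[1]
                + (G * k - 2) * np.log(s2)
            )
            return obj, (lam * s2, s2, beta)

        # coarse log-grid, then two local refinements around the best point
        grid = np.exp(np.linspace(-8, 8, 4000))
        for _ in range(3):
            evals = [dense_profile(lam) for lam in grid]
            i_best = int(np.argmin([e[0] for e in evals]))
            best = evals[i_best]
            lo = grid[max(i_best - 1, 0)]
            hi = grid[min(i_best + 1, len(grid) - 1)]
            grid = np.linspace(lo, hi, 400)
        sb2, sw2, beta = best[1]
        assert fit.components.sigma2_between == pytest.approx(sb2, rel=1e-5)
        assert fit.components.sigma2_within == pytest.approx(sw2, rel=1e-5)
        assert fit.fixed_effects["x"] == pytest.approx(beta[1], abs=1e-5)

    def test_between_subject_covariate_reduces_sigma_b(self):
        """Adjusting for a real between-subject shift (contraceptive use
        on the log scale) shrinks the between variance: in nearly every
        replicate for a strong effect (1.5 sigma_b group difference), and
        on average already for a modest one (0.5 sigma_b), where the REML
        degrees-of-freedom correction leaves the per-replicate comparison
        noisy."""
        from biovariation import CovariateSpec

        def deltas(shift_mult, n_rep):
            out = []
            for i in range(n_rep):
                spec = single_biomarker_spec(0.6, seed=70_000 + i)
                sigma_b = math.sqrt(
                    math.log(spec.biomarkers["marker"].cv_g ** 2 + 1)
                )
                spec.covariates = {
                    "contraceptive": CovariateSpec(bernoulli_p=0.5)
                }
                spec.biomarkers["marker"].effects = {
                    "contraceptive": shift_mult * sigma_b
                }
                table = generate_cohort(spec)
                crude = fit_oneway_random(table, "marker", "log")
                adj = fit_mixed_covariates(
                    table, "marker", ["contraceptive"], "log"
                )
                out.append(
                    crude.components.sigma2_between
                    - adj.components.sigma2_between
                )
            return np.asarray(out)

        strong = deltas(1.5, 200)
        assert (strong > 0).mean() >= 0.95
        modest = deltas(0.5, 200)
        assert modest.mean() > 0


class TestBootstrap:
    def test_deterministic_given_seed(self, default_cohort):
        a = bootstrap_icc_ci(default_cohort, "uric_acid", scale="log", B=100, seed=5)
        b = bootstrap_icc_ci(default_cohort, "uric_acid", scale="log", B=100, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_degenerate_repeats_give_unit_interval(self):
        df = pd.DataFrame(
            {
                "subject": np.repeat(list("ABCDE"), 3),
                "visit": np.tile([1, 2, 3], 5),
                "marker": np.repeat([3.0, 5.0, 7.0, 11.0, 13.0], 3),
            }
        )
        table = MeasurementTable(data=df, biomarkers=["marker"], n_visits=3)
        res = bootstrap_icc_ci(table, "marker", B=50, seed=1)
        assert res.ci_low == res.ci_high == 1.0

    def test_ci_order_enforced(self):
        with pytest.raises(ValueError):
            ICCResult(icc=0.5, ci_low=0.8, ci_high=0.2, n_boot=10)


class TestResidualExclusion:
    def test_no_offenders_is_noop(self):
        spec = single_biomarker_spec(0.7, seed=31)
        table = generate_cohort(spec)
        fit, report = iterative_residual_exclusion(
            table, "marker", scale="log", cutoff=50.0
        )
        assert report.iterations == 0
        base = fit_oneway_random(table, "marker", "log")
        assert fit.components.sigma2_between == pytest.approx(
            base.components.sigma2_between
        )

    def test_injected_shift_subject_excluded(self):
        """A +6 sigma_w single-visit shift is caught in the first round in
        almost every replicate, and its removal shrinks sigma_w^2."""
        caught = 0
        shrunk = 0
        n_rep = 200
        for i in range(n_rep):
            spec = single_biomarker_spec(0.6, seed=90_000 + i)
            table = generate_cohort(spec)
            df = table.data.copy()
            sigma_w = math.sqrt(math.log(0.2**2 + 1))
            target = (df["subject"] == "S001") & (df["visit"] == 2)
            df.loc[target, "marker"] *= math.exp(6 * sigma_w)
            table = MeasurementTable(
                data=df, biomarkers=["marker"], covariates=table.covariates,
                n_visits=3,
            )
            before = fit_oneway_random(table, "marker", "log")
            fit, report = iterative_residual_exclusion(
                table, "marker", scale="log", cutoff=2.0
            )
            first_round = [
                e.subject_id for e in report.excluded_subjects
            ]
            if "S001" in first_round:
                caught += 1
            if fit.components.sigma2_within < before.components.sigma2_within:
                shrunk += 1
        assert caught / n_rep >= 0.99
        assert shrunk / n_rep >= 0.95

    def test_bad_cutoff_rejected(self, toy_table):
        with pytest.raises(ValueError):
            iterative_residual_exclusion(toy_table, "marker", cutoff=0.0)
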