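"""Closed-form metric tests, anchored to published reliability-table cells."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from biovariation import (
    SampleSizeParams,
    VarianceComponents,
    cv_from_components,
    cv_from_sigma,
    icc_category,
    icc_sample_size,
    index_of_individuality,
    n_measurements,
    n_measurements_from_icc,
    rcv_asymmetric,
    rcv_symmetric,
    sigma_from_cv,
)


class TestCVSigmaConversion:
    def test_zero_maps_to_zero(self):
        assert sigma_from_cv(0.0) == 0.0
        assert cv_from_sigma(0.0) == 0.0

    def test_direct_value(self):
        assert sigma_from_cv(0.113) == pytest.approx(0.11264, abs=5e-6)

    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_roundtrip_inverse(self, cv):
        assert cv_from_sigma(sigma_from_cv(cv)) == pytest.approx(cv, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_cv(-0.1)


class TestRCV:
    @pytest.mark.parametrize(
        "cv_t, up, down",
        [
            (0.113, 36.6, -26.8),  # serum uric acid
            (0.310, 131.6, -56.8),  # gamma-tocopherol
            (0.186, 66.7, -40.0),  # retinol
            (0.101, 32.2, -24.4),  # beta-carotene, restricted subgroup
        ],
    )
    def test_asymmetric_reproduces_printed_cells(self, cv_t, up, down):
        got_up, got_down = rcv_asymmetric(cv_t, z=1.96)
        assert round(got_up, 1) == up
        assert round(got_down, 1) == down

    @pytest.mark.parametrize(
        "cv_t, expected", [(0.161, 44.6), (0.062, 17.2), (0.0, 0.0)]
    )
    def test_symmetric_reproduces_printed_cells(self, cv_t, expected):
        assert round(rcv_symmetric(cv_t, z=1.96), 1) == expected

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_up_exceeds_down_magnitude(self, cv_t):
        up, down = rcv_asymmetric(cv_t)
        assert up > abs(down) > 0

    def test_small_cv_agrees_with_symmetric(self):
        # exp(+-x) - 1 = +-x + x^2/2 + ..., so each side deviates by ~x/2
        # (about 1.4% at cv=0.01, z=1.96) and the symmetrized mean by ~x^2/6
        up, down = rcv_asymmetric(0.01)
        sym = rcv_symmetric(0.01)
        assert up == pytest.approx(sym, rel=0.02)
        assert -down == pytest.approx(sym, rel=0.02)
        assert (up - down) / 2 == pytest.approx(sym, rel=1e-3)


class TestIndexOfIndividuality:
    @pytest.mark.parametrize(
        "cv_t, cv_g, expected",
        [(0.217, 0.617, 0.352), (0.266, 0.547, 0.487), (0.161, 0.053, 3.038)],
    )
    def test_printed_cells(self, cv_t, cv_g, expected):
        assert index_of_individuality(cv_t, cv_g) == pytest.approx(
            expected, abs=0.01
        )

    def test_zero_cvg_is_undefined(self):
        assert index_of_individuality(0.07, 0.0) is None

    @given(st.floats(min_value=1e-6, max_value=10))
    def test_equal_cvs_give_unity(self, c):
        assert index_of_individuality(c, c) == pytest.approx(1.0)


class TestNMeasurements:
    @pytest.mark.parametrize(
        "icc, attenuation, expected",
        [
            (0.098, 0.10, 83),  # glutathione
            (0.098, 0.20, 37),
            (0.515, 0.10, 9),  # vitamin C
            (0.875, 0.10, 2),  # beta-carotene: raw 1.286, excess > 0.20
            (0.875, 0.20, 1),  # raw 0.571, floored at 1
            (0.567, 0.10, 7),  # bilirubin
            (0.567, 0.20, 3),  # raw 3.055, excess 0.055 <= 0.20 rounds down
            (0.5, 0.10, 9),  # exactly 9.0, no rounding
        ],
    )
    def test_rounding_rule_matches_printed_cells(self, icc, attenuation, expected):
        assert n_measurements_from_icc(icc, attenuation) == expected

    def test_zero_between_variance_undefined(self):
        assert n_measurements(0.07, 0.0, 0.10) is None
        assert n_measurements_from_icc(0.0, 0.10) is None

    def test_monotone_in_icc_and_attenuation(self):
        iccs = np.linspace(0.05, 0.95, 19)
        n10 = [n_measurements_from_icc(i, 0.10) for i in iccs]
        n20 = [n_measurements_from_icc(i, 0.20) for i in iccs]
        assert all(a >= b for a, b in zip(n10, n10[1:]))
        assert all(a >= b for a, b in zip(n10, n20))


class TestCVFromComponents:
    def test_log_scale(self):
        vc = VarianceComponents(0.01, 0.01, 4.5, scale="log")
        cv_g, cv_t = cv_from_components(vc)
        assert cv_g == pytest.approx(0.10025, abs=1e-4)
        assert cv_t == pytest.approx(0.10025, abs=1e-4)

    def test_singular_between_gives_zero_cvg(self):
        vc = VarianceComponents(0.0, 0.005, 1.11, scale="raw", singular=True)
        cv_g, _ = cv_from_components(vc)
        assert cv_g == 0.0

    def test_raw_scale(self):
        vc = VarianceComponents(0.0, 1.0, 10.0, scale="raw", singular=True)
        _, cv_t = cv_from_components(vc)
        assert cv_t == pytest.approx(0.1)

    def test_raw_scale_needs_positive_mean(self):
        vc = VarianceComponents(1.0, 1.0, 0.0, scale="raw")
        with pytest.raises(ValueError):
            cv_from_components(vc)


class TestICCCategory:
    @pytest.mark.parametrize(
        "icc, expected",
        [
            (0.875, "very_good"),
            (0.75, "very_good"),
            (0.693, "good"),
            (0.51, "good"),
            (0.40, "fair"),
            (0.098, "poor"),
            (0.0, "poor"),
        ],
    )
    def test_bands(self, icc, expected):
        assert icc_category(icc) == expected

    def test_gap_between_bands_warns_and_is_fair(self):
        with pytest.warns(UserWarning):
            assert icc_category(0.505) == "fair"


class TestSampleSize:
    def test_detecting_icc_030_with_three_visits(self):
        out = icc_sample_size(SampleSizeParams(rho1=0.30, k=3, dropout=0.20))
        assert out["n_raw"] == pytest.approx(35.455, abs=0.01)
        assert out["n_required"] == 36
        assert out["n_with_dropout"] == 44

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeParams(rho1=0.3, rho0=0.5)

    def test_power_by_monte_carlo_f_test(self):
        """The analytic n=36 design should reach >= 80% power at ICC 0.30
        against 0, judged by the one-way ANOVA F-test over 10,000 cohorts."""
        rng = np.random.default_rng(2024)
        n, k, icc = 36, 3, 0.30
        reps = 10_000
        b = rng.standard_normal((reps, n, 1)) * math.sqrt(icc)
        e = rng.standard_normal((reps, n, k)) * math.sqrt(1 - icc)
        y = b + e
        gm = y.mean(axis=(1, 2), keepdims=True)
        sub_means = y.mean(axis=2)
        ssb = k * ((sub_means - gm[:, :, 0]) ** 2).sum(axis=1)
        ssw = ((y - sub_means[:, :, None]) ** 2).sum(axis=(1, 2))
        f = (ssb / (n - 1)) / (ssw / (n * (k - 1)))
        pvals = stats.f.sf(f, n - 1, n * (k - 1))
        assert (pvals < 0.05).mean() >= 0.80
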