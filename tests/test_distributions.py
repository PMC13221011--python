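"""Unit and property tests for the two distribution families.

Oracles: adaptive quadrature (scipy.integrate.quad) for normalization and
moments, scipy.stats.skewnorm as an independent implementation of the skew
family, and the closed-form skew-normal moment formulas.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from flowrosetta.distributions import (
    KURT_G2_RANGE,
    ShapeParams,
    alpha_from_skewness,
    beta_from_excess_kurtosis,
    kurt_excess_kurtosis,
    kurt_gauss_cdf,
    kurt_gauss_pdf,
    kurt_norm_const,
    kurt_var_factor,
    sample_kurt,
    sample_skew,
    shape_moments,
    skew_gauss_cdf,
    skew_gauss_pdf,
    skew_skewness,
)

SHAPE_GRID = [-5.0, -1.0, -0.3, 0.0, 0.3, 1.0, 5.0]


def closed_form_skewnorm_gamma1(alpha):
    d = alpha / math.sqrt(1 + alpha * alpha)
    m = d * math.sqrt(2 / math.pi)
    return (4 - math.pi) / 2 * m**3 / (1 - m * m) ** 1.5


class TestSkewFamily:
    def test_value_at_location(self):
        # z = 0 forces the modulation to 1/2 regardless of alpha
        for alpha in SHAPE_GRID:
            p = ShapeParams(3.0, 1.0, alpha=alpha)
            assert skew_gauss_pdf(3.0, p) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-12)

    def test_reduces_to_normal_at_zero_shape(self):
        x = np.linspace(-6, 9, 101)
        p = ShapeParams(1.5, 2.0, alpha=0.0)
        np.testing.assert_allclose(skew_gauss_pdf(x, p), stats.norm.pdf(x, 1.5, 2.0),
                                   rtol=0, atol=1e-15)

    @pytest.mark.parametrize("alpha", SHAPE_GRID)
    def test_integrates_to_one(self, alpha):
        p = ShapeParams(0.0, 2.0, alpha=alpha)
        total, err = integrate.quad(lambda x: skew_gauss_pdf(x, p), -24, 24, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_skewnorm(self):
        # independent implementation of the same family
        x = np.linspace(-5, 5, 51)
        for alpha in (-2.0, 0.7, 4.0):
            p = ShapeParams(0.5, 1.3, alpha=alpha)
            np.testing.assert_allclose(skew_gauss_pdf(x, p),
                                       stats.skewnorm.pdf(x, alpha, 0.5, 1.3), rtol=1e-10)
            np.testing.assert_allclose(skew_gauss_cdf(x, p),
                                       stats.skewnorm.cdf(x, alpha, 0.5, 1.3), atol=1e-9)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            ShapeParams(0.0, -1.0, alpha=1.0)
        with pytest.raises(ValueError):
            ShapeParams(0.0, 1.0)  # no shape at all
        with pytest.raises(ValueError):
            ShapeParams(0.0, 1.0, alpha=0.0, beta=0.0)  # both shapes
        with pytest.raises(ValueError):
            skew_gauss_pdf(np.array([np.inf]), ShapeParams(0.0, 1.0, alpha=1.0))


class TestKurtFamily:
    def test_normalization_constant_quadrature(self):
        # raw (unnormalized) form integrates to C(beta); C(1) = 1.5 exactly
        for beta in (1.0, 0.4, -0.8):
            raw, _ = integrate.quad(
                lambda z: 2 * stats.norm.pdf(z) * stats.norm.cdf(beta * abs(z)), -15, 15,
                limit=200)
            assert raw == pytest.approx(kurt_norm_const(beta), abs=1e-8)
        assert kurt_norm_const(1.0) == pytest.approx(1.5, abs=1e-12)

    def test_reduces_to_normal_at_zero_shape(self):
        y = np.linspace(-8, 8, 101)
        p = ShapeParams(0.0, 1.5, beta=0.0)
        np.testing.assert_allclose(kurt_gauss_pdf(y, p), stats.norm.pdf(y, 0, 1.5),
                                   rtol=0, atol=1e-15)

    @pytest.mark.parametrize("beta", SHAPE_GRID)
    def test_integrates_to_one_and_symmetric(self, beta):
        p = ShapeParams(1.0, 2.0, beta=beta)
        total, _ = integrate.quad(lambda y: kurt_gauss_pdf(y, p), -30, 32, limit=300)
        assert total == pytest.approx(1.0, abs=1e-8)
        d = np.linspace(0.1, 6, 23)
        np.testing.assert_allclose(kurt_gauss_pdf(1.0 + d, p), kurt_gauss_pdf(1.0 - d, p),
                                   rtol=1e-12)

    @pytest.mark.parametrize("beta", [-1.0, -0.3, 0.5, 2.0])
    def test_cdf_matches_quadrature(self, beta):
        p = ShapeParams(0.5, 1.2, beta=beta)
        for y in (-2.0, 0.0, 0.5, 1.7):
            num, _ = integrate.quad(lambda t: kurt_gauss_pdf(t, p), -20, y, limit=300)
            assert kurt_gauss_cdf(y, p) == pytest.approx(num, abs=1e-9)

    @pytest.mark.parametrize("beta", [-2.0, -0.85, 0.0, 0.7, 3.0])
    def test_closed_form_moments_match_quadrature(self, beta):
        p = ShapeParams(0.0, 1.0, beta=beta)
        m2, _ = integrate.quad(lambda z: z * z * kurt_gauss_pdf(z, p), -15, 15, limit=300)
        m4, _ = integrate.quad(lambda z: z**4 * kurt_gauss_pdf(z, p), -15, 15, limit=300)
        assert kurt_var_factor(beta) == pytest.approx(m2, abs=1e-8)
        assert kurt_excess_kurtosis(beta) == pytest.approx(m4 / m2**2 - 3, abs=1e-7)


class TestSamplers:
    def test_skew_sampler_symmetric_case(self):
        rng = np.random.default_rng(7)
        x = sample_skew(200_000, ShapeParams(0.0, 1.0, alpha=0.0), rng)
        assert abs(stats.skew(x)) < 0.02

    def test_skew_sampler_matches_closed_form_skewness(self):
        rng = np.random.default_rng(8)
        x = sample_skew(500_000, ShapeParams(0.0, 1.0, alpha=5.0), rng)
        expected = closed_form_skewnorm_gamma1(5.0)
        assert expected == pytest.approx(0.851, abs=1e-3)
        assert stats.skew(x) == pytest.approx(expected, abs=0.01)

    def test_deterministic_given_seed(self):
        a = sample_skew(1000, ShapeParams(0.0, 1.0, alpha=2.0), np.random.default_rng(3))
        b = sample_skew(1000, ShapeParams(0.0, 1.0, alpha=2.0), np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        c = sample_kurt(1000, ShapeParams(0.0, 1.0, beta=1.0), np.random.default_rng(3))
        d = sample_kurt(1000, ShapeParams(0.0, 1.0, beta=1.0), np.random.default_rng(3))
        np.testing.assert_array_equal(c, d)

    def test_kurt_sampler_reduction_ks(self):
        rng = np.random.default_rng(9)
        y = sample_kurt(10_000, ShapeParams(2.0, 3.0, beta=0.0), rng)
        ref = rng.normal(2.0, 3.0, 10_000)
        assert stats.ks_2samp(y, ref).pvalue > 0.01

    def test_kurt_sampler_mean_unbiased(self):
        rng = np.random.default_rng(10)
        p = ShapeParams(5.0, 2.0, beta=2.0)
        y = sample_kurt(100_000, p, rng)
        se = y.std() / math.sqrt(y.size)
        assert abs(y.mean() - 5.0) < 3 * se

    def test_rejection_acceptance_rate_identity(self):
        # accepting z ~ N(0,1) with probability Phi(beta |z|) must succeed at
        # rate C(beta)/2; this is the envelope identity the sampler relies on
        rng = np.random.default_rng(11)
        beta = 1.0
        z = rng.standard_normal(100_000)
        u = rng.random(100_000)
        rate = float(np.mean(u < stats.norm.cdf(beta * np.abs(z))))
        assert kurt_norm_const(beta) / 2 == pytest.approx(0.75, abs=1e-12)
        assert rate == pytest.approx(0.75, abs=0.01)

    @pytest.mark.parametrize("family,shape", [("skew", s) for s in SHAPE_GRID]
                             + [("kurt", s) for s in SHAPE_GRID])
    def test_sampler_pdf_agreement_ks(self, family, shape):
        rng = np.random.default_rng(12)
        n = 10_000
        if family == "skew":
            p = ShapeParams(0.0, 1.0, alpha=shape)
            x = sample_skew(n, p, rng)
            res = stats.kstest(x, lambda v: skew_gauss_cdf(v, p))
        else:
            p = ShapeParams(0.0, 1.0, beta=shape)
            x = sample_kurt(n, p, rng)
            res = stats.kstest(x, lambda v: kurt_gauss_cdf(v, p))
        crit = 1.628 / math.sqrt(n)  # 1% critical value
        assert res.statistic < crit

    def test_sample_skewness_monotone_in_alpha(self):
        vals = []
        for alpha in SHAPE_GRID:
            x = sample_skew(100_000, ShapeParams(0.0, 1.0, alpha=alpha),
                            np.random.default_rng(13))
            vals.append(stats.skew(x))
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_skew(0, ShapeParams(0.0, 1.0, alpha=0.0), np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample_kurt(-5, ShapeParams(0.0, 1.0, beta=0.0), np.random.default_rng(0))


class TestMoments:
    def test_zero_shapes_give_zero_moments(self):
        assert shape_moments(ShapeParams(0, 1, alpha=0.0)) == (0.0, 0.0)
        assert shape_moments(ShapeParams(0, 1, beta=0.0)) == (0.0, 0.0)

    def test_alpha5_skewness(self):
        g1, g2 = shape_moments(ShapeParams(0, 1, alpha=5.0))
        assert g1 == pytest.approx(0.851, abs=1e-3)
        assert g2 > 0

    def test_skew_moments_match_quadrature(self):
        p = ShapeParams(0.0, 1.0, alpha=2.0)
        m1, _ = integrate.quad(lambda x: x * skew_gauss_pdf(x, p), -12, 12)
        m2, _ = integrate.quad(lambda x: x * x * skew_gauss_pdf(x, p), -12, 12)
        m3, _ = integrate.quad(lambda x: x**3 * skew_gauss_pdf(x, p), -12, 12)
        var = m2 - m1 * m1
        g1 = (m3 - 3 * m1 * var - m1**3) / var**1.5
        assert skew_skewness(2.0) == pytest.approx(g1, abs=1e-8)

    @given(st.floats(-0.97, 0.97))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_alpha_inversion_round_trip(self, g1):
        assert skew_skewness(alpha_from_skewness(g1)) == pytest.approx(g1, abs=1e-9)

    @given(st.floats(KURT_G2_RANGE[0] + 1e-3, KURT_G2_RANGE[1] - 1e-3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_beta_inversion_round_trip(self, g2):
        assert kurt_excess_kurtosis(beta_from_excess_kurtosis(g2)) == pytest.approx(g2, abs=1e-8)

    def test_beta_inversion_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            beta_from_excess_kurtosis(1.5)
        with pytest.raises(ValueError):
            beta_from_excess_kurtosis(-0.6)
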