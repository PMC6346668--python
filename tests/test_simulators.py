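"""Simulator correctness: copula algebra, sampling law, BOLD model, VAR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from cddnet import (
    AsymCopulaSpec,
    BOLDSimSpec,
    VARSpec,
    asym_copula_cdf,
    cyclic_var_matrix,
    gaussianize,
    plackett_cdf,
    sample_asym_copula,
    simulate_bold,
    simulate_var,
    var_power_matrix,
    var_stationary_cov,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def plackett_oracle(u: float, v: float, theta: float) -> float:
    """Independent Plackett evaluation: root of the odds-ratio equation.

    C solves theta = C(1-u-v+C) / ((u-C)(v-C)) on (max(0,u+v-1), min(u,v)).
    """
    if u in (0.0, 1.0) or v in (0.0, 1.0) or abs(theta - 1) < 1e-12:
        return u * v

    def eq(c):
        return c * (1 - u - v + c) - theta * (u - c) * (v - c)

    lo, hi = max(0.0, u + v - 1.0), min(u, v)
    return optimize.brentq(eq, lo + 1e-14, hi - 1e-14, xtol=1e-13)


class TestPlackett:
    def test_margins_and_independence(self):
        u = np.linspace(0.05, 0.95, 7)
        np.testing.assert_allclose(plackett_cdf(u, 1.0, 5.0), u, atol=1e-12)
        np.testing.assert_allclose(plackett_cdf(u, 0.0, 5.0), 0.0, atol=1e-12)
        # theta -> 1 limit branch returns the independence copula
        assert plackett_cdf(0.5, 0.5, 1.0) == pytest.approx(0.25, abs=1e-12)
        # continuity across the limit branch
        assert plackett_cdf(0.3, 0.6, 1 + 1e-7) == pytest.approx(0.18, abs=1e-6)

    def test_closed_form_against_root_oracle(self):
        assert plackett_cdf(0.5, 0.5, 5.0) == pytest.approx(0.34549, abs=5e-6)
        rng = np.random.default_rng(3)
        for _ in range(50):
            u, v = rng.uniform(0.01, 0.99, 2)
            theta = rng.uniform(0.05, 50)
            assert plackett_cdf(u, v, theta) == pytest.approx(
                plackett_oracle(u, v, theta), abs=1e-9
            )

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            plackett_cdf(0.5, 0.5, 0.0)
        with pytest.raises(ValueError):
            plackett_cdf(0.5, 0.5, -2.0)

    @settings(derandomize=True, max_examples=100)
    @given(u1=unit, u2=unit, v1=unit, v2=unit,
           theta=st.floats(min_value=0.05, max_value=100.0))
    def test_two_increasing(self, u1, u2, v1, v2, theta):
        ua, ub = sorted((u1, u2))
        va, vb = sorted((v1, v2))
        mass = (
            plackett_cdf(ub, vb, theta)
            - plackett_cdf(ua, vb, theta)
            - plackett_cdf(ub, va, theta)
            + plackett_cdf(ua, va, theta)
        )
        assert mass >= -1e-12


class TestAsymCopula:
    def test_margin_condition(self, model3_copula):
        u = np.linspace(0.1, 0.9, 9)
        np.testing.assert_allclose(asym_copula_cdf(u, 1.0, model3_copula), u, atol=1e-12)
        np.testing.assert_allclose(asym_copula_cdf(1.0, u, model3_copula), u, atol=1e-12)

    def test_symmetric_when_alpha_equals_beta(self):
        spec = AsymCopulaSpec(theta1=5000, theta2=5, alpha=0.4, beta=0.4)
        g = np.linspace(0.1, 0.9, 5)
        uu, vv = np.meshgrid(g, g)
        np.testing.assert_allclose(
            asym_copula_cdf(uu, vv, spec), asym_copula_cdf(vv, uu, spec), atol=1e-12
        )

    def test_factorization_against_oracle(self):
        spec = AsymCopulaSpec(theta1=5000, theta2=5, alpha=0.9, beta=0.1)
        u, v = 0.3, 0.7
        expected = plackett_oracle(u**0.9, v**0.1, 5000) * plackett_oracle(
            u**0.1, v**0.9, 5
        )
        assert asym_copula_cdf(u, v, spec) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_exponents_reduce_to_plackett(self):
        g = np.linspace(0.05, 0.95, 7)
        uu, vv = np.meshgrid(g, g)
        spec1 = AsymCopulaSpec(theta1=7.0, theta2=3.0, alpha=1.0, beta=1.0)
        np.testing.assert_allclose(
            asym_copula_cdf(uu, vv, spec1), plackett_cdf(uu, vv, 7.0), atol=1e-12
        )
        spec0 = AsymCopulaSpec(theta1=7.0, theta2=3.0, alpha=0.0, beta=0.0)
        np.testing.assert_allclose(
            asym_copula_cdf(uu, vv, spec0), plackett_cdf(uu, vv, 3.0), atol=1e-12
        )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            AsymCopulaSpec(theta1=-1, theta2=5, alpha=0.5, beta=0.5)
        with pytest.raises(ValueError):
            AsymCopulaSpec(theta1=5, theta2=5, alpha=1.5, beta=0.5)


class TestSampling:
    def test_uniform_margins(self, model3_copula):
        uv = sample_asym_copula(10000, model3_copula, seed=1)
        assert stats.kstest(uv[:, 0], "uniform").pvalue > 0.01
        assert stats.kstest(uv[:, 1], "uniform").pvalue > 0.01

    def test_empirical_cdf_matches_cdf_oracle(self, model3_copula):
        n = 20000
        uv = sample_asym_copula(n, model3_copula, seed=2)
        grid = np.linspace(1 / 6, 5 / 6, 5)
        for gu in grid:
            for gv in grid:
                emp = np.mean((uv[:, 0] <= gu) & (uv[:, 1] <= gv))
                theo = asym_copula_cdf(gu, gv, model3_copula)
                mc_se = np.sqrt(theo * (1 - theo) / n)
                assert abs(emp - theo) < 3 * mc_se + 1e-4

    def test_reproducible(self, model3_copula):
        a = sample_asym_copula(50, model3_copula, seed=7)
        b = sample_asym_copula(50, model3_copula, seed=7)
        np.testing.assert_array_equal(a, b)


class TestGaussianize:
    def test_values_and_monotonicity(self):
        assert gaussianize([0.5])[0] == pytest.approx(0.0, abs=1e-12)
        assert gaussianize([0.975])[0] == pytest.approx(1.95996, abs=1e-5)
        u = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(gaussianize(u)) > 0)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            gaussianize([0.0, 0.5])
        with pytest.raises(ValueError):
            gaussianize([0.5, 1.0])


class TestSimulateBold:
    def test_lengths(self):
        spec = BOLDSimSpec(T_minutes=15, a=0.1, fwhm=4.0, tr=2.0)
        assert spec.n_latent == 9000
        x = np.random.default_rng(0).standard_normal(9000)
        xs, ys = simulate_bold(x, x, spec)
        assert len(xs) == len(ys) == 450

    def test_degenerate_kernel_is_pure_subsampling(self):
        spec = BOLDSimSpec(T_minutes=1, a=0.5, fwhm=0.0, tr=1.0)
        x = np.arange(120, dtype=float)
        xs, _ = simulate_bold(x, x, spec)
        np.testing.assert_array_equal(xs, x[::2])

    def test_constant_preserved(self):
        spec = BOLDSimSpec(T_minutes=1, a=0.1, fwhm=4.0, tr=2.0)
        x = np.full(600, 3.25)
        xs, _ = simulate_bold(x, x, spec)
        np.testing.assert_allclose(xs, 3.25, atol=1e-12)

    def test_tr_not_multiple_of_a(self):
        with pytest.raises(ValueError):
            BOLDSimSpec(T_minutes=1, a=0.3, fwhm=4.0, tr=1.0)

    def test_wrong_input_length(self):
        spec = BOLDSimSpec(T_minutes=1, a=0.1, tr=2.0)
        with pytest.raises(ValueError):
            simulate_bold(np.zeros(10), np.zeros(10), spec)


class TestSimulateVar:
    def test_white_noise_passthrough_correlation(self):
        spec = VARSpec(A=np.zeros((3, 3)), noise_model="dependent", r12=0.7, n=20000, L=1)
        y = simulate_var(spec, seed=4)
        assert np.corrcoef(y[:, 0], y[:, 1])[0, 1] == pytest.approx(0.7, abs=0.02)

    def test_sample_cov_matches_lyapunov_oracle(self, var_A):
        spec = VARSpec(A=var_A, noise_model="dependent", r12=0.56, n=60000, L=1)
        y = simulate_var(spec, seed=5)
        Q = np.eye(3)
        Q[0, 1] = Q[1, 0] = 0.56
        S = var_stationary_cov(var_A, Q)
        assert S[0, 0] == pytest.approx(4 / 3, abs=1e-12)
        np.testing.assert_allclose(np.cov(y.T), S, atol=0.06)

    def test_subsampled_path_follows_power_matrix(self, var_A):
        spec = VARSpec(A=var_A, noise_model="independent", n=50000, L=5)
        y = simulate_var(spec, seed=6)
        X, Y = y[:-1], y[1:]
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        np.testing.assert_allclose(coef.T, var_power_matrix(var_A, 5), atol=0.05)

    def test_asymmetric_noise_standardized(self, var_A, model3_copula):
        spec = VARSpec(
            A=np.zeros((3, 3)), noise_model="asymmetric",
            copula_spec=model3_copula, n=20000, L=1,
        )
        y = simulate_var(spec, seed=8)
        # noise feeds straight through: components should be standardized
        assert np.std(y[:, 0]) == pytest.approx(1.0, abs=0.05)
        assert abs(np.mean(y[:, 0])) < 0.05

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError):
            VARSpec(A=np.eye(3), noise_model="independent")

    def test_output_length(self, var_A):
        spec = VARSpec(A=var_A, noise_model="independent", n=10000, L=5)
        assert simulate_var(spec, seed=0).shape == (2000, 3)


class TestVarPowerMatrix:
    def test_identity_and_powers(self, var_A):
        np.testing.assert_array_equal(var_power_matrix(var_A, 1), var_A)
        A2 = var_power_matrix(var_A, 2)
        expected2 = np.zeros((3, 3))
        expected2[0, 2] = expected2[1, 0] = expected2[2, 1] = 0.25
        np.testing.assert_allclose(A2, expected2, atol=1e-15)
        A5 = var_power_matrix(var_A, 5)
        expected5 = np.zeros((3, 3))
        expected5[0, 2] = expected5[1, 0] = expected5[2, 1] = 0.5**5
        np.testing.assert_allclose(A5, expected5, atol=1e-15)

    def test_reversal_of_influences(self, var_A):
        # lag-one influences 2->1, 3->2, 1->3 flip after subsampling
        assert var_A[0, 1] != 0 and var_power_matrix(var_A, 5)[0, 1] == 0
        assert var_power_matrix(var_A, 5)[0, 2] != 0 and var_A[0, 2] == 0

    def test_invalid_exponent(self, var_A):
        with pytest.raises(ValueError):
            var_power_matrix(var_A, 0)
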