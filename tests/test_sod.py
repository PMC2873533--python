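import numpy as np
import pytest
from scipy import stats

from sodpcr import (
    build_reference,
    correlation_t_test,
    ks_normality,
    mahalanobis_d2,
    multivariate_normality_d2,
    sod_test,
)

MU = np.array([46.41, 23.89, 8.61])
SIGMA = np.array(
    [[6.07**2, 12.0, 3.0],
     [12.0, 2.86**2, 2.0],
     [3.0, 2.0, 1.20**2]]
)  # positive definite, Table-scale variances with plausible covariances


def _reference(rng, n=72):
    return build_reference(rng.multivariate_normal(MU, SIGMA, size=n))


def cofactor_inverse(a):
    """Explicit 3x3 inverse via the adjugate — brute-force oracle."""
    c = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(a, i, axis=0), j, axis=1)
            c[i, j] = (-1) ** (i + j) * np.linalg.det(minor)
    return c.T / np.linalg.det(a)


class TestReference:
    def test_identical_fingerprints_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            build_reference(np.tile(MU, (20, 1)))

    def test_too_few_runs_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            build_reference(rng.multivariate_normal(MU, SIGMA, size=5))

    def test_small_reference_warns(self, rng):
        with pytest.warns(UserWarning, match="approximate"):
            build_reference(rng.multivariate_normal(MU, SIGMA, size=15))

    def test_parameter_recovery(self, rng):
        n = 5000
        ref = build_reference(rng.multivariate_normal(MU, SIGMA, size=n))
        se = np.sqrt(np.diag(SIGMA) / n)
        assert np.all(np.abs(ref.mu - MU) < 3 * se)
        assert np.linalg.norm(ref.sigma - SIGMA) < 0.1 * np.linalg.norm(SIGMA)


class TestMahalanobis:
    def test_distance_zero_at_mean(self, rng):
        ref = _reference(rng)
        res = sod_test(ref.mu, ref)
        assert res.d2 == pytest.approx(0.0, abs=1e-12)
        assert not res.is_outlier

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        ref = _reference(rng)
        ref2 = type(ref)(mu=ref.mu, sigma=np.eye(3), n_ref=ref.n_ref)
        y = ref.mu + np.array([1.0, 2.0, 2.0])
        res = sod_test(y, ref2)
        assert res.d2 == pytest.approx(9.0, rel=1e-12)
        assert res.is_outlier  # 9 > 7.81

    def test_agrees_with_cofactor_inverse_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(size=(3, 3))
            sigma = a @ a.T + 0.5 * np.eye(3)
            mu = rng.normal(size=3)
            ref = build_reference(rng.multivariate_normal(mu, sigma, size=40))
            y = rng.normal(size=3)
            expected = (y - ref.mu) @ cofactor_inverse(ref.sigma) @ (y - ref.mu)
            assert mahalanobis_d2(y, ref) == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance(self, rng):
        pts = rng.multivariate_normal(MU, SIGMA, size=72)
        tests = rng.multivariate_normal(MU, SIGMA, size=10)
        ref = build_reference(pts)
        d2 = mahalanobis_d2(tests, ref)
        for _ in range(5):
            m = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            offset = rng.normal(size=3) * 10
            ref_t = build_reference(pts @ m.T + offset)
            d2_t = mahalanobis_d2(tests @ m.T + offset, ref_t)
            np.testing.assert_allclose(d2_t, d2, rtol=1e-8)

    def test_reference_d2_sums_to_3_n_minus_1(self, rng):
        pts = rng.multivariate_normal(MU, SIGMA, size=72)
        ref = build_reference(pts)
        assert mahalanobis_d2(pts, ref).sum() == pytest.approx(3 * 71, abs=1e-8)

    def test_non_finite_fingerprint_rejected(self, rng):
        ref = _reference(rng)
        with pytest.raises(ValueError, match="non-finite"):
            sod_test(np.array([np.nan, 1.0, 2.0]), ref)

    def test_null_calibration_flag_rate(self, rng):
        flags = 0
        for _ in range(20):
            ref = _reference(rng, n=72)
            draws = rng.multivariate_normal(MU, SIGMA, size=100)
            flags += int(np.sum(mahalanobis_d2(draws, ref) > stats.chi2.ppf(0.95, 3)))
        assert 0.03 <= flags / 2000 <= 0.08


class TestKsNormality:
    def test_null_behavior(self, rng):
        z, p = ks_normality(rng.normal(1.88, 0.02, 500))
        assert z < 1.5 and p > 0.01

    def test_scaling_convention_matches_sqrt_n_d(self, rng):
        x = rng.normal(0, 1, 72)
        d = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
        z, p = ks_normality(x)
        assert z == pytest.approx(np.sqrt(72) * d)
        assert p == pytest.approx(float(stats.kstwobign.sf(z)))

    def test_bimodal_mixture_rejected(self, rng):
        x = np.concatenate([rng.normal(-5, 0.3, 50), rng.normal(5, 0.3, 50)])
        _, p = ks_normality(x)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ks_normality(np.full(20, 1.88))


class TestCorrelationTTest:
    def test_zero_correlation(self):
        values = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        lg = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        r, r2, t, p = correlation_t_test(values, lg)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_reference_scale_r2_and_p(self, rng):
        # R^2 = 0.017 at n = 72 corresponds to a two-sided p of about 0.28
        r = np.sqrt(0.017)
        n = 72
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(0.28, abs=0.01)
        # and the implementation reproduces that closed form on matching data
        g = rng.normal(size=n)
        noise = rng.normal(size=n)
        noise -= np.polyval(np.polyfit(g, noise, 1), g)  # orthogonalize
        x = r * (g - g.mean()) / g.std() + np.sqrt(1 - r**2) * noise / noise.std()
        r_hat, r2_hat, t_hat, p_hat = correlation_t_test(x, g)
        assert r2_hat == pytest.approx(0.017, abs=1e-6)
        assert p_hat == pytest.approx(p, abs=1e-6)

    def test_perfect_correlation_limit(self):
        g = np.linspace(0, 1, 20)
        r, r2, t, p = correlation_t_test(2 * g + 1, g)
        assert p < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_t_test(np.full(10, 3.0), np.linspace(0, 1, 10))


class TestMultivariateNormality:
    def test_qq_correlation_near_one_for_normal_reference(self, rng):
        pts = rng.multivariate_normal(MU, SIGMA, size=500)
        ref = build_reference(pts)
        table, qq_r = multivariate_normality_d2(pts, ref)
        assert qq_r > 0.99
        assert table["d2"].is_monotonic_increasing
        assert len(table) == 500
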