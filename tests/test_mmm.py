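import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr, ndtri

from mltscan import (
    BernsteinBasis,
    ModelSpec,
    StackedFit,
    encode_response,
    equicoordinate_quantile,
    fit,
    joint_covariance,
    max_t_inference,
    mvn_rectangle,
)


def _equicorrelated(k, rho):
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


class TestMvnRectangle:
    def test_univariate_closed_form(self):
        r = mvn_rectangle(np.eye(1), 1.959964)
        assert r.prob == pytest.approx(0.95, abs=1e-4)

    def test_sidak_two_independent(self):
        # (2*Phi(c) - 1)^2 = 0.95 at c ~ 2.2365
        r = mvn_rectangle(np.eye(2), 2.2365)
        assert r.prob == pytest.approx(0.95, abs=1e-3)

    def test_perfect_correlation_collapses_to_univariate(self):
        r = mvn_rectangle(_equicorrelated(4, 1.0), 1.959964)
        assert r.prob == pytest.approx(0.95, abs=1e-3)

    def test_matches_independent_genz_implementation(self):
        """Cross-check against scipy's own MVN integrator on a non-trivial R."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + 5 * np.eye(5)
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        c = 2.4
        ours = mvn_rectangle(R, c, tol=5e-5).prob
        ref = stats.multivariate_normal(mean=np.zeros(5), cov=R, seed=1).cdf(
            np.full(5, c), lower_limit=np.full(5, -c)
        )
        assert ours == pytest.approx(ref, abs=2e-3)

    def test_deterministic_given_seed(self):
        R = _equicorrelated(6, 0.4)
        a = mvn_rectangle(R, 2.5, seed=99)
        b = mvn_rectangle(R, 2.5, seed=99)
        assert a.prob == b.prob

    def test_non_psd_beyond_tolerance_errors(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues (3, -1)
        with pytest.raises(ValueError):
            mvn_rectangle(R, 2.0)


class TestEquicoordinateQuantile:
    def test_single_test_is_unadjusted(self):
        assert equicoordinate_quantile(np.eye(1)) == pytest.approx(1.96, abs=0.005)

    def test_sidak_root_two_independent(self):
        target = ndtri(0.5 * (1 + np.sqrt(0.95)))
        assert equicoordinate_quantile(np.eye(2)) == pytest.approx(target, abs=1e-3)

    def test_duplicated_tests_fall_back_to_single(self):
        assert equicoordinate_quantile(_equicorrelated(3, 1.0)) == pytest.approx(
            1.959964, abs=1e-3
        )

    @pytest.mark.parametrize("k,rho", [(5, 0.0), (20, 0.5), (120, 0.0)])
    def test_bracketed_by_unadjusted_and_bonferroni(self, k, rho):
        crit = equicoordinate_quantile(_equicorrelated(k, rho), seed=3)
        bonf = ndtri(1 - 0.025 / k)
        assert 1.9599 <= crit <= bonf + 1e-9

    def test_monotone_in_family_size_for_independent_tests(self):
        crits = [equicoordinate_quantile(np.eye(k)) for k in (1, 2, 5, 20)]
        assert all(a <= b + 1e-3 for a, b in zip(crits, crits[1:]))


class TestJointCovariance:
    @staticmethod
    def _fit_pair(ycols, x, tie_policy="none"):
        fits = []
        for j, y in enumerate(ycols):
            resp = encode_response(y, name=f"m{j}", tie_policy=tie_policy)
            spec = ModelSpec(basis=BernsteinBasis(2, resp.support), covariate_names=("x",))
            fits.append(fit(spec, resp, x[:, None]))
        return fits

    def test_independent_metabolites_nearly_uncorrelated(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(18, 80, 500)
        fits = self._fit_pair([rng.normal(size=500), rng.normal(size=500)], x)
        stacked = StackedFit(fits, [("m0", "a"), ("m1", "a")], [3, 3], 500)
        cov, kept = joint_covariance(stacked)
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert kept == [0, 1]
        assert abs(r) < 0.1

    def test_duplicated_metabolite_fully_correlated(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(18, 80, 300)
        y = rng.normal(size=300)
        fits = self._fit_pair([y, y.copy()], x)
        stacked = StackedFit(fits, [("m0", "a"), ("m0b", "a")], [3, 3], 300)
        cov, _ = joint_covariance(stacked)
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert r > 0.999

    def test_single_model_reproduces_own_sandwich(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(18, 80, 200)
        (f,) = self._fit_pair([rng.normal(size=200)], x)
        stacked = StackedFit([f], [("m0", "a")], [3], 200)
        cov, _ = joint_covariance(stacked)
        assert cov.shape == (1, 1)
        assert cov[0, 0] == pytest.approx(f.covariance[3, 3], rel=1e-8)


class TestMaxTInference:
    def test_single_model_equals_wald(self):
        ji = max_t_inference([0.5], np.array([[0.04]]))
        assert ji.crit == pytest.approx(1.96, abs=0.005)
        assert ji.ci_lower[0] == pytest.approx(0.5 - 1.959964 * 0.2, abs=1e-3)

    def test_adjusted_p_dominates_unadjusted(self, rng):
        k = 8
        effects = rng.normal(scale=0.3, size=k)
        cov = 0.02 * _equicorrelated(k, 0.3)
        ji = max_t_inference(effects, cov, seed=5)
        t = np.abs(effects / ji.se)
        p_un = 2 * ndtr(-t)
        assert np.all(ji.p_adj >= p_un - 1e-12)

    def test_ci_and_p_value_flags_agree(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            k = 6
            effects = r.normal(scale=0.4, size=k)
            cov = 0.03 * _equicorrelated(k, 0.2)
            ji = max_t_inference(effects, cov, seed=seed)
            from_ci = (ji.ci_lower > 0) | (ji.ci_upper < 0)
            from_p = ji.p_adj < 1 - ji.level
            np.testing.assert_array_equal(from_ci, from_p)

    def test_deterministic_given_seed(self):
        effects = [0.1, -0.3, 0.2]
        cov = 0.01 * _equicorrelated(3, 0.5)
        a = max_t_inference(effects, cov, seed=77)
        b = max_t_inference(effects, cov, seed=77)
        np.testing.assert_array_equal(a.p_adj, b.p_adj)
        assert a.crit == b.crit

    def test_nonpositive_variance_names_model(self):
        with pytest.raises(ValueError, match="gudca"):
            max_t_inference([0.1, 0.2], np.diag([0.01, 0.0]), labels=["c10", "gudca"])
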