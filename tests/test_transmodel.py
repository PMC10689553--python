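import numpy as np
import pytest
from scipy.stats import norm

from mltscan import (
    AlignmentError,
    BernsteinBasis,
    ModelSpec,
    NotConvergedError,
    encode_response,
    fit,
    loglik,
    score_per_obs,
)
from mltscan.bernstein import gamma_from_theta
from mltscan.response import CensoredValue, Kind, ResponseVector


def _gaussian_sample(n=500, beta=0.5, sigma=10.0, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.uniform(18, 80, n)
    y = 2.0 + beta * x + rng.normal(0, sigma, n)
    return x, y


@pytest.fixture(scope="module")
def gaussian_fit():
    x, y = _gaussian_sample()
    resp = encode_response(y, name="gauss")
    spec = ModelSpec(basis=BernsteinBasis(1, resp.support), covariate_names=("x",))
    return x, y, resp, spec, fit(spec, resp, x[:, None])


class TestLoglik:
    def test_matches_reparameterized_normal_density(self, gaussian_fit):
        """With a linear h (order 1) and probit link on exact data, the model
        is an ordinary Gaussian regression in disguise."""
        x, y, resp, spec, f = gaussian_fit
        a, b = resp.support
        sigma = (b - a) / (f.theta[1] - f.theta[0])
        mu = sigma * (x * f.beta[0] - f.theta[0]) + a
        closed_form = norm.logpdf(y, mu, sigma).sum()
        assert f.loglik == pytest.approx(closed_form, abs=1e-6)

    def test_left_censored_at_latent_zero_gives_log_half(self):
        # one observation censored where h(bound) - x'beta = 0: contribution log(Phi(0))
        values = (
            CensoredValue.left(0.0),
            CensoredValue.exact(-1.0),
            CensoredValue.exact(1.0),
        )
        resp = ResponseVector("v", values, support=(-2.0, 2.0))
        spec = ModelSpec(basis=BernsteinBasis(1, (-2.0, 2.0)), covariate_names=("x",))
        # theta = (-2, 2) makes h the identity on (-2, 2); h(0) = 0
        gamma = gamma_from_theta(np.array([-2.0, 2.0]))
        X = np.zeros((3, 1))
        ll_all = loglik(spec, np.concatenate([gamma, [0.0]]), resp, X)
        resp_noc = ResponseVector("v", values[1:], support=(-2.0, 2.0))
        ll_noc = loglik(spec, np.concatenate([gamma, [0.0]]), resp_noc, np.zeros((2, 1)))
        assert ll_all - ll_noc == pytest.approx(np.log(0.5), abs=1e-12)

    def test_interval_covering_support_contributes_log_one(self):
        values = (
            CensoredValue.interval(-30.0, 30.0),
            CensoredValue.exact(-1.0),
            CensoredValue.exact(1.0),
        )
        resp = ResponseVector("v", values, support=(-30.0, 30.0))
        spec = ModelSpec(basis=BernsteinBasis(1, (-30.0, 30.0)), covariate_names=("x",))
        gamma = gamma_from_theta(np.array([-30.0, 30.0]))  # h spans +-30 latent units
        resp_noc = ResponseVector("v", values[1:], support=(-30.0, 30.0))
        delta = loglik(spec, np.concatenate([gamma, [0.0]]), resp, np.zeros((3, 1))) - loglik(
            spec, np.concatenate([gamma, [0.0]]), resp_noc, np.zeros((2, 1))
        )
        assert delta == pytest.approx(0.0, abs=1e-6)

    def test_misaligned_rows_error(self, gaussian_fit):
        x, y, resp, spec, _ = gaussian_fit
        with pytest.raises(AlignmentError):
            loglik(spec, np.zeros(3), resp, x[:10, None])


class TestFit:
    def test_beta_matches_ols_slope_over_residual_sd(self, gaussian_fit):
        x, y, resp, spec, f = gaussian_fit
        slope, icpt = np.polyfit(x, y, 1)
        resid = y - (slope * x + icpt)
        target = slope / np.std(resid)
        assert f.converged
        assert f.beta[0] == pytest.approx(target, rel=0.01)

    def test_score_column_sums_vanish_at_mle(self, gaussian_fit):
        *_, f = gaussian_fit
        assert np.max(np.abs(f.scores.sum(axis=0))) < 1e-5

    def test_info_positive_definite_at_mle(self, gaussian_fit):
        *_, f = gaussian_fit
        assert np.all(np.linalg.eigvalsh(f.info) > 0)

    def test_scale_equivariance_of_beta(self):
        """Multiplying the response by a positive constant is absorbed by h."""
        x, y = _gaussian_sample(n=300, seed=5)
        out = []
        for scale in (1.0, 37.5):
            resp = encode_response(y * scale, name="s")
            spec = ModelSpec(basis=BernsteinBasis(4, resp.support), covariate_names=("x",))
            f = fit(spec, resp, x[:, None])
            out.append((f.beta[0], f.loglik - np.sum(np.log(scale) * 0)))
        assert out[0][0] == pytest.approx(out[1][0], abs=1e-6)
        # loglik shifts by -n*log(scale) (Jacobian of the rescaling), nothing else
        n = len(y)
        assert out[0][1] - (out[1][1] + n * np.log(37.5)) == pytest.approx(0.0, abs=1e-4)

    def test_censoring_robustness_of_beta(self):
        """Re-encoding the lowest decile as left-censored moves beta by less
        than one joint standard error."""
        x, y = _gaussian_sample(n=400, seed=9)
        r_full = encode_response(y, name="full")
        spec = ModelSpec(basis=BernsteinBasis(4, r_full.support), covariate_names=("x",))
        f_full = fit(spec, r_full, x[:, None])
        loq = np.quantile(y, 0.1)
        r_cens = encode_response(y, loq=loq, name="cens", support=r_full.support)
        f_cens = fit(spec, r_cens, x[:, None])
        se = f_full.se_beta[0]
        assert f_cens.converged
        assert abs(f_cens.beta[0] - f_full.beta[0]) < se

    def test_null_fit_rarely_significant(self):
        """Under independence, |beta| < 3 se in nearly all replicates."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.uniform(18, 80, 200)
            y = np.exp(rng.normal(size=200))  # monotone-distorted null
            resp = encode_response(y, name="null")
            spec = ModelSpec(basis=BernsteinBasis(4, resp.support), covariate_names=("x",))
            f = fit(spec, resp, x[:, None])
            if f.converged and abs(f.beta[0]) > 3 * f.se_beta[0]:
                hits += 1
        assert hits <= 2

    def test_too_few_observations_rejected(self):
        resp = encode_response([1.0, 2.0, 3.0, 4.0], name="tiny")
        spec = ModelSpec(basis=BernsteinBasis(4, resp.support), covariate_names=("x",))
        with pytest.raises(ValueError, match="identify"):
            fit(spec, resp, np.arange(4.0)[:, None])

    def test_logit_link_fits_and_orders_effects(self):
        x, y = _gaussian_sample(n=300, beta=0.8, seed=11)
        resp = encode_response(y, name="l")
        spec = ModelSpec(
            basis=BernsteinBasis(4, resp.support), covariate_names=("x",), link="logit"
        )
        f = fit(spec, resp, x[:, None])
        assert f.converged
        assert f.beta[0] > 0  # log-odds effect keeps the direction


class TestObservedInformation:
    @pytest.mark.parametrize("link", ["probit", "logit"])
    def test_analytic_matches_finite_difference(self, link):
        """The closed-form information agrees with a numerical Jacobian of the
        analytic gradient on mixed exact/censored/interval data."""
        from mltscan import transmodel as tm

        rng = np.random.default_rng(17)
        x = rng.uniform(18, 80, 120)
        y = np.round(rng.normal(size=120) + 0.01 * x, 1)
        loq = float(np.quantile(y, 0.15))
        resp = encode_response(y, loq=loq, name="mix")
        spec = ModelSpec(
            basis=BernsteinBasis(3, resp.support), covariate_names=("x",), link=link
        )
        prep = tm._Prepared(spec, resp, x[:, None])
        params = tm._start_values(prep, spec) + rng.normal(scale=0.2, size=spec.n_params)
        analytic = tm._observed_information(prep, tm._LINKS[link], params)
        numeric = tm._fd_information(prep, tm._LINKS[link], params)
        scale = max(1.0, np.max(np.abs(numeric)))
        assert np.max(np.abs(analytic - numeric)) / scale < 1e-6


class TestScorePerObs:
    def test_zero_rows_for_missing_samples(self):
        x, y = _gaussian_sample(n=100, seed=3)
        y[::7] = np.nan
        resp = encode_response(y, name="m")
        spec = ModelSpec(basis=BernsteinBasis(3, resp.support), covariate_names=("x",))
        f = fit(spec, resp, x[:, None])
        S = score_per_obs(spec, f, resp, x[:, None])
        assert S.shape[0] == 100
        assert np.all(S[::7] == 0)
        assert np.max(np.abs(S.sum(axis=0))) < 1e-5

    def test_finite_difference_agreement_random_rows(self, gaussian_fit):
        x, y, resp, spec, f = gaussian_fit
        S = score_per_obs(spec, f, resp, x[:, None])
        params = np.concatenate([f.gamma, f.beta])
        rng = np.random.default_rng(0)
        rows = rng.choice(len(y), 5, replace=False)
        for i in rows:
            sub_resp = ResponseVector("one", (resp.values[i],), support=resp.support)
            for j in range(params.size):
                h = 1e-6 * (1 + abs(params[j]))
                up, dn = params.copy(), params.copy()
                up[j] += h
                dn[j] -= h
                fd = (
                    loglik(spec, up, sub_resp, x[i : i + 1, None])
                    - loglik(spec, dn, sub_resp, x[i : i + 1, None])
                ) / (2 * h)
                assert fd == pytest.approx(S[i, j], abs=1e-5)

    def test_duplicated_data_doubles_rows(self):
        x, y = _gaussian_sample(n=80, seed=13)
        resp = encode_response(y, name="d", tie_policy="none")
        spec = ModelSpec(basis=BernsteinBasis(2, resp.support), covariate_names=("x",))
        f = fit(spec, resp, x[:, None])
        x2 = np.concatenate([x, x])
        resp2 = encode_response(np.concatenate([y, y]), name="d2", tie_policy="none",
                                support=resp.support)
        S2 = score_per_obs(spec, f, resp2, x2[:, None])
        S1 = score_per_obs(spec, f, resp, x[:, None])
        assert S2.shape[0] == 2 * S1.shape[0]
        np.testing.assert_allclose(S2.sum(axis=0), 2 * S1.sum(axis=0), atol=1e-8)

    def test_requires_converged_fit(self, gaussian_fit):
        x, y, resp, spec, f = gaussian_fit
        import dataclasses

        broken = dataclasses.replace(f, converged=False)
        with pytest.raises(NotConvergedError):
            score_per_obs(spec, broken, resp, x[:, None])

    def test_all_contributions_finite_at_mle(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(18, 80, 150)
        y = np.round(rng.normal(size=150) + 0.01 * x, 1)  # ties via rounding
        loq = float(np.quantile(y, 0.1))
        resp = encode_response(y, loq=loq, name="mix")
        spec = ModelSpec(basis=BernsteinBasis(4, resp.support), covariate_names=("x",))
        f = fit(spec, resp, x[:, None])
        params = np.concatenate([f.gamma, f.beta])
        ll = loglik(spec, params, resp, x[:, None])
        assert np.isfinite(ll)
        assert np.all(np.isfinite(f.scores))
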