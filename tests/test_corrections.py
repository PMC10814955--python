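"""Score cumulants, matching priors and bias-reduced estimators."""

import math

import numpy as np
import pytest
from scipy import stats

import fbstev as fb
from fbstev import corrections


# --------------------------------------------------------------------------
# cumulants and corrections, closed forms
# --------------------------------------------------------------------------

def test_cumulants_closed_forms():
    rate = fb.exponential_rate_model()
    cum = fb.cumulants_scalar(rate, [2.0], n=8)
    assert cum.kappa2 == pytest.approx(8 / 4.0)
    assert cum.kappa3 == pytest.approx(-2 * 8 / 8.0)
    assert cum.kappa1 == 0.0

    pois = fb.poisson_logmean_model()
    for th in (-1.0, 0.0, 2.0):
        c = fb.cumulants_scalar(pois, [th], n=5)
        assert c.kappa3 / c.kappa2 == pytest.approx(1.0)

    assert fb.cumulants_scalar(fb.SkewNormalShape(), [0.0], n=3).kappa3 == \
        pytest.approx(0.0, abs=1e-10)


def test_monte_carlo_cumulants_match_closed_form():
    rate = fb.exponential_rate_model()
    mc = fb.cumulants_scalar(rate, [1.0], n=10, method="monte-carlo",
                             replicates=4000, seed=2)
    exact = fb.cumulants_scalar(rate, [1.0], n=10)
    assert mc.method == "monte-carlo"
    assert abs(mc.kappa2 - exact.kappa2) < 4 * mc.mc_standard_errors[1]
    assert abs(mc.kappa3 - exact.kappa3) < 4 * mc.mc_standard_errors[2]


def test_median_correction_values():
    rate = fb.exponential_rate_model()
    for th in (0.5, 1.0, 3.0):
        cum = fb.cumulants_scalar(rate, [th], n=6)
        assert fb.median_correction_scalar(cum) == pytest.approx(-1 / (3 * th))
    pois = fb.poisson_logmean_model()
    cum = fb.cumulants_scalar(pois, [0.7], n=4)
    assert fb.median_correction_scalar(cum) == pytest.approx(1 / 6)
    assert fb.median_correction_scalar(cum, "as-displayed") == \
        pytest.approx(-1 / 6)


def test_firth_correction_values():
    rate = fb.exponential_rate_model()
    assert fb.firth_correction_scalar(rate, [2.0], n=5) == pytest.approx(-0.5)
    scale = fb.ExponentialScale()
    assert fb.firth_correction_scalar(scale, [1.7], n=5) == pytest.approx(0.0,
                                                                          abs=1e-12)
    nv = fb.NormalVariance()
    assert fb.firth_correction_scalar(nv, [0.8], n=5) == pytest.approx(0.0,
                                                                       abs=1e-12)


def test_matching_prior_canonical_exponents():
    """Median prior ∝ i^{1/6}, Firth/Jeffreys ∝ i^{1/2} in canonical families."""
    rate = fb.exponential_rate_model()
    grid = np.linspace(0.4, 3.0, 301)
    log_i = np.array([math.log(float(rate.expected_info([t], n=1)[0, 0]))
                      for t in grid])
    for kind, expo in (("median", 1 / 6), ("firth", 1 / 2),
                       ("jeffreys", 1 / 2)):
        lp = fb.matching_logprior_scalar(rate, kind, grid)
        resid = lp - expo * log_i
        assert np.ptp(resid) < 1e-8, kind


def test_matching_prior_exponential_scale_exponent():
    """m = 1/(3θ) integrates to the θ^{1/3} prior for the scale model."""
    scale = fb.ExponentialScale()
    grid = np.linspace(0.5, 4.0, 201)
    lp = fb.matching_logprior_scalar(scale, "median", grid)
    resid = lp - np.log(grid) / 3.0
    assert np.ptp(resid) < 1e-8
    assert np.allclose(fb.matching_logprior_scalar(scale, "none", grid), 0.0)


# --------------------------------------------------------------------------
# modified-score solver
# --------------------------------------------------------------------------

def test_solve_modified_score_closed_forms(flat_exp_data):
    n, ybar = 10, 2.0
    scale_fit = fb.solve_modified_score(fb.ExponentialScale(), flat_exp_data,
                                        "median")
    assert scale_fit.value == pytest.approx(n * ybar / (n - 1 / 3), abs=1e-8)
    assert scale_fit.converged and scale_fit.standard_error > 0

    rate_fit = fb.solve_modified_score(fb.exponential_rate_model(),
                                       flat_exp_data, "median")
    assert rate_fit.value == pytest.approx((n - 1 / 3) / (n * ybar), abs=1e-9)

    firth_rate = fb.solve_modified_score(fb.exponential_rate_model(),
                                         flat_exp_data, "firth")
    assert firth_rate.value == pytest.approx((n - 1) / (n * ybar), abs=1e-9)


def test_solve_modified_score_poisson_zero_counts():
    """All-zero Poisson counts: flat MLE is −∞, the median root is finite."""
    pois = fb.poisson_logmean_model()
    data = fb.Dataset.from_values([0.0] * 5)
    fit = fb.solve_modified_score(pois, data, "median")
    assert fit.value == pytest.approx(math.log(1 / 30.0), abs=1e-8)
    with pytest.raises(fb.DivergenceError) as err:
        fb.solve_modified_score(pois, data, "none")
    assert err.value.direction == -1


def test_estimator_equivariance(exp_scale_data):
    base = fb.ExponentialScale()
    est = fb.solve_modified_score(base, exp_scale_data, "median").value
    tlog = fb.TransformedScalarModel(base, math.log, math.exp,
                                     (-np.inf, np.inf))
    trec = fb.TransformedScalarModel(base, lambda t: 1 / t, lambda p: 1 / p,
                                     (0.0, np.inf))
    assert fb.solve_modified_score(tlog, exp_scale_data, "median").value == \
        pytest.approx(math.log(est), abs=1e-6)
    assert fb.solve_modified_score(trec, exp_scale_data, "median").value == \
        pytest.approx(1 / est, abs=1e-6)


def test_median_unbiasedness_oracle():
    """P(θ̃ ≤ θ0) ≈ 1/2 for the median-kind estimator; the MLE is off-centre.

    Exponential scale model, n = 10, θ0 = 1; the median-kind root is
    available in closed form (n ȳ/(n − 1/3)), so 10⁵ replicates are a single
    vectorized computation.  Equivariance transfers the statement to the
    rate parameterization for free.
    """
    n, theta0, reps = 10, 1.0, 100000
    rng = np.random.default_rng(77)
    ybar = rng.gamma(n, scale=theta0 / n, size=reps)
    est = n * ybar / (n - 1 / 3)
    p_median = float(np.mean(est <= theta0))
    p_mle = float(np.mean(ybar <= theta0))
    assert 0.495 <= p_median <= 0.505
    assert not (0.47 <= p_mle <= 0.53) or p_mle < 0.47 or p_mle > 0.53
    assert p_mle > 0.53  # Gamma(n) median sits below its mean
    # spot-check the closed form against the solver on one replicate
    d = fb.Dataset.from_values(rng.exponential(theta0, n))
    fit = fb.solve_modified_score(fb.ExponentialScale(), d, "median")
    assert fit.value == pytest.approx(n * d.y.mean() / (n - 1 / 3), abs=1e-8)


def test_firth_mean_unbiasedness():
    """Canonical exponential rate: the Firth root (n−1)/(n ȳ) has mean θ0."""
    n, theta0, reps = 10, 2.0, 100000
    rng = np.random.default_rng(5)
    ybar = rng.gamma(n, scale=1 / (n * theta0), size=reps)  # mean 1/θ0
    est = (n - 1) / (n * ybar)
    se = float(np.std(est) / math.sqrt(reps))
    assert abs(float(np.mean(est)) - theta0) < 3 * se


# --------------------------------------------------------------------------
# profile machinery
# --------------------------------------------------------------------------

def test_profile_loglik_normal_closed_form(normal_mean_data):
    model, data = normal_mean_data
    psi = 0.4
    lp, lam = fb.profile_loglik(model, psi, data)
    assert lam[0] == pytest.approx(float(np.mean((data.y - psi) ** 2)))
    theta_hat = fb.full_mle(model, data)
    lp_hat, _ = fb.profile_loglik(model, float(theta_hat[0]), data)
    assert lp_hat == pytest.approx(model.loglik(theta_hat, data), abs=1e-9)
    assert lp < lp_hat


def test_profile_loglik_logistic_matches_refit(logistic_regular):
    model, data = logistic_regular
    lp, lam = fb.profile_loglik(model, 0.5, data, interest_index=1)
    from scipy.optimize import minimize
    res = minimize(lambda l: -model.loglik(np.array([l[0], 0.5, l[1], l[2]]),
                                           data),
                   np.zeros(3), method="BFGS", options={"gtol": 1e-10})
    assert lp == pytest.approx(-res.fun, abs=1e-8)


def test_profile_score(normal_mean_data, logistic_regular):
    model, data = normal_mean_data
    psi = 0.4
    lam = float(np.mean((data.y - psi) ** 2))
    expected = len(data) * (float(np.mean(data.y)) - psi) / lam
    assert fb.profile_score(model, psi, data) == pytest.approx(expected,
                                                               rel=1e-8)
    # zero at the MLE
    mle = fb.full_mle(model, data)
    assert abs(fb.profile_score(model, float(mle[0]), data)) < 1e-6
    # finite-difference agreement on a logistic profile
    lmodel, ldata = logistic_regular
    h = 1e-5
    lp_plus, _ = fb.profile_loglik(lmodel, 0.5 + h, ldata, interest_index=1)
    lp_minus, _ = fb.profile_loglik(lmodel, 0.5 - h, ldata, interest_index=1)
    fd = (lp_plus - lp_minus) / (2 * h)
    assert fb.profile_score(lmodel, 0.5, ldata, interest_index=1) == \
        pytest.approx(fd, rel=1e-5, abs=1e-6)


def test_profile_cumulants_normal_mean(normal_mean_data):
    model, data = normal_mean_data
    cum = fb.profile_cumulants(model, 1.0, data, replicates=2000, seed=3)
    assert cum.kappa2 > 0
    assert cum.method == "monte-carlo"
    assert abs(cum.kappa1) < 4 * cum.mc_standard_errors[0]
    assert abs(cum.kappa3) < 4 * cum.mc_standard_errors[2]


def test_profile_cumulants_no_nuisance_reduces_to_scalar(flat_exp_data):
    rate = fb.exponential_rate_model()
    closed = fb.profile_cumulants(rate, 0.5, flat_exp_data)
    exact = fb.cumulants_scalar(rate, [0.5], data=flat_exp_data)
    assert closed.kappa2 == exact.kappa2 and closed.kappa3 == exact.kappa3


def test_median_correction_profile_reduces_to_scalar():
    cum = fb.ScoreCumulants(0.0, 2.0, -1.2, "closed-form-canonical")
    assert fb.median_correction_profile(cum) == \
        pytest.approx(fb.median_correction_scalar(cum))
    shifted = fb.ScoreCumulants(0.3, 2.0, -1.2, "monte-carlo")
    assert fb.median_correction_profile(shifted) == \
        pytest.approx(-0.3 - 1.2 / 12.0)


def test_solve_modified_profile_score_no_nuisance(flat_exp_data):
    rate = fb.exponential_rate_model()
    scalar = fb.solve_modified_score(rate, flat_exp_data, "median")
    prof = fb.solve_modified_profile_score(rate, flat_exp_data,
                                           correction="median", seed=1)
    assert prof.value == pytest.approx(scalar.value, abs=1e-6)


def test_separated_logistic_gets_finite_median_estimate(separated_logistic):
    model, data = separated_logistic
    fit = fb.solve_modified_profile_score(model, data, correction="median",
                                          replicates=120, seed=11,
                                          cache_points=11)
    assert np.isfinite(fit.value) and 0 < fit.value < 30
    assert fit.standard_error > 0
    # the unpenalized fit diverges on the same data (statsmodels oracle)
    import statsmodels.api as sm
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mle = sm.Logit(data.y, data.design()).fit(disp=0, maxiter=500,
                                                  method="bfgs")
    assert abs(mle.params[1]) > fit.value  # drifts beyond the penalized root


# --------------------------------------------------------------------------
# Firth-penalized logistic regression
# --------------------------------------------------------------------------

def test_firth_logistic_intercept_only():
    """k successes of n: the Jeffreys-penalized mode is logit((k+1/2)/(n+1))."""
    X = np.ones((20, 1))
    y = np.r_[np.ones(4), np.zeros(16)]
    beta = fb.firth_logistic_fit(X, y)
    assert beta[0] == pytest.approx(math.log(4.5 / 16.5), abs=1e-8)


def test_firth_logistic_separation_and_rank(separated_logistic):
    model, data = separated_logistic
    beta = fb.firth_logistic_fit(data.design(), data.y)
    assert np.all(np.isfinite(beta)) and 0 < beta[1] < 20
    bad = np.column_stack([data.design(), data.design()[:, 1]])
    with pytest.raises(ValueError):
        fb.firth_logistic_fit(bad, data.y)


def test_firth_logistic_approaches_mle_for_large_n():
    model = fb.LogisticRegression(covariates=("x",))
    data = model.simulate(np.array([0.2, 0.7]), 5000, np.random.default_rng(1))
    beta_f = fb.firth_logistic_fit(data.design(), data.y)
    beta_mle = fb.full_mle(model, data)
    assert np.max(np.abs(beta_f - beta_mle)) < 5e-3
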