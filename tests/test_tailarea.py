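"""Higher-order tail-area machinery: rp, qB, rB* and the third-order e-value."""

import math

import numpy as np
import pytest
from scipy import stats

import fbstev as fb
from fbstev.models import gamma_rate_model


@pytest.fixture(scope="module")
def normal_ctx():
    model = fb.NormalMeanKnownVariance(1.0)
    data = model.simulate([0.0], 15, np.random.default_rng(0))
    return model, data, fb.make_context(model, data)


def test_normal_case_is_exact(normal_ctx):
    """Flat prior/reference, known variance: qB = rp, so Φ(rB*) is exact."""
    model, data, ctx = normal_ctx
    n = len(data)
    ybar = float(np.mean(data.y))
    for psi in (ybar - 1.1, ybar - 0.3, ybar + 0.8):
        rp = fb.profile_likelihood_root(ctx, psi)
        assert rp == pytest.approx(math.sqrt(n) * (ybar - psi), abs=1e-9)
        assert fb.qB_factor(ctx, psi) == pytest.approx(rp, abs=1e-9)
        rstar = fb.rstar_bayes(ctx, psi)
        assert not rstar.interpolated
        assert rstar.rstar == pytest.approx(rp, abs=1e-8)
        exact_tail = stats.norm.cdf(math.sqrt(n) * (ybar - psi))
        assert fb.tail_area_probability(ctx, psi) == pytest.approx(exact_tail,
                                                                   abs=1e-8)


def test_profile_root_properties(normal_ctx):
    _, data, ctx = normal_ctx
    assert fb.profile_likelihood_root(ctx, ctx.psi_hat) == 0.0
    psi = ctx.psi_hat - 0.7
    rp = fb.profile_likelihood_root(ctx, psi)
    lr = 2 * (ctx.lp_hat - ctx.profile_loglik(psi))
    assert rp ** 2 == pytest.approx(lr, rel=1e-12)
    assert rp > 0  # ψ below ψ̂ ⇒ positive root


def test_qB_sign_matches_rp_near_mode():
    model = gamma_rate_model(2.0)
    data = model.simulate([1.0], 25, np.random.default_rng(7))
    ctx = fb.make_context(model, data)
    se = 1 / math.sqrt(ctx.jp_hat)
    for eps in (-0.6, -0.25, 0.25, 0.6):
        psi = ctx.psi_hat + eps * se
        assert math.copysign(1, fb.qB_factor(ctx, psi)) == \
            math.copysign(1, fb.profile_likelihood_root(ctx, psi))


def test_singular_window_interpolation(normal_ctx):
    _, _, ctx = normal_ctx
    se = 1 / math.sqrt(ctx.jp_hat)
    near = ctx.psi_hat + 0.001 * se
    res = fb.rstar_bayes(ctx, near)
    assert res.interpolated
    # continuity across the window: interpolated values straddle zero smoothly
    left = fb.rstar_bayes(ctx, ctx.psi_hat - 0.02 * se).rstar
    right = fb.rstar_bayes(ctx, ctx.psi_hat + 0.02 * se).rstar
    assert left > 0 > right
    assert abs(left) < 0.1 and abs(right) < 0.1
    assert fb.tail_area_probability(ctx, ctx.psi_hat) == pytest.approx(0.5,
                                                                       abs=0.01)


def _oracle_error(model, n, exact_posterior, rel_dev=1.5):
    """|Φ(rB*) − exact flat-prior posterior tail| at a fixed z-deviation.

    Data are n copies of 1.0, so the flat-prior posterior of the model's
    parameter is conjugate and the tail is available in closed form; with no
    nuisance parameters the Laplace marginal equals that posterior exactly,
    making the closed form the quadrature oracle without grid error.
    """
    data = fb.Dataset.from_values(np.full(n, 1.0))
    ctx = fb.make_context(model, data)
    psi0 = ctx.psi_hat * (1 - rel_dev / math.sqrt(n))
    return abs(fb.tail_area_probability(ctx, psi0)
               - float(exact_posterior(n).sf(psi0)))


@pytest.mark.parametrize("make_model,posterior", [
    (fb.ExponentialScale,
     lambda n: stats.invgamma(n - 1, scale=n)),
    (lambda: gamma_rate_model(3.0),
     lambda n: stats.gamma(3 * n + 1, scale=1 / n)),
], ids=["exponential-scale", "gamma-rate"])
def test_tail_area_matches_posterior_oracle(make_model, posterior):
    """Φ(rB*) third-order accuracy against the exact posterior tail."""
    model = make_model()
    err15 = _oracle_error(model, 15, posterior)
    err60 = _oracle_error(model, 60, posterior)
    assert err15 < 1e-3
    assert err60 < 1e-4
    # third-order decay: the error ratio tracks (15/60)^{3/2} within factor 3
    assert err60 / err15 < 3 * (15 / 60) ** 1.5


def test_evalue_tailarea_symmetric_and_mode(normal_ctx):
    _, data, ctx = normal_ctx
    ybar = float(np.mean(data.y))
    psi0 = ybar - 0.5
    res = fb.evalue_tailarea(ctx, fb.Hypothesis(psi0))
    rstar = fb.rstar_bayes(ctx, psi0).rstar
    assert res.ev == pytest.approx(2 * (1 - stats.norm.cdf(abs(rstar))),
                                   abs=1e-6)
    at_mode = fb.evalue_tailarea(ctx, fb.Hypothesis(ctx.psi_hat))
    assert at_mode.ev == pytest.approx(1.0, abs=1e-9)


def test_evalue_tailarea_matches_exact_grid_on_gamma_toy():
    model = gamma_rate_model(2.0)
    data = model.simulate([1.0], 30, np.random.default_rng(3))
    ctx = fb.make_context(model, data)
    psi0 = ctx.psi_hat * 0.72
    res = fb.evalue_tailarea(ctx, fb.Hypothesis(psi0))
    grid = np.linspace(ctx.psi_hat * 0.1, ctx.psi_hat * 6, 20001)
    marg = fb.laplace_marginal_posterior(ctx, grid)
    exact = fb.evalue_exact_1d(marg, fb.Hypothesis(psi0))
    assert 0 <= res.ev <= 1
    assert res.ev == pytest.approx(exact.ev, abs=5e-3)


def test_laplace_marginal_normal_nuisance_matches_exact_marginal():
    """Flat prior: the Laplace form reproduces the Student-type marginal."""
    from scipy.integrate import quad

    model = fb.NormalMeanVariance()
    data = model.simulate([0.0, 1.0], 30, np.random.default_rng(8))
    ctx = fb.make_context(model, data)
    ybar = float(np.mean(data.y))
    s2 = float(np.var(data.y))
    grid = np.linspace(ybar - 1.5, ybar + 1.5, 801)
    marg = fb.laplace_marginal_posterior(ctx, grid)
    coarse = grid[::40]

    def exact(mu):
        val, _ = quad(lambda v: math.exp(model.loglik([mu, v], data)
                                         - model.loglik([ybar, s2], data)),
                      1e-3, 20.0, limit=200)
        return val

    ex = np.array([exact(m) for m in coarse])
    ex /= np.trapezoid(ex, coarse)
    la = marg.density_at(coarse)
    la /= np.trapezoid(la, coarse)
    assert np.max(np.abs(ex - la)) < 0.01


def test_bivariate_regression_tailarea_with_invwishart_prior():
    """Correlation-coefficient e-value via rB* with an IW(1, I) prior on Σ.

    The tail-area route with a full prior avoids the 5-dimensional
    integration a full-posterior FBST would need.
    """
    data = fb.generate_fixture("bivariate-regression", 13)
    model = fb.BivariateRegression()
    ctx = fb.make_context(model, data,
                          prior=fb.tailarea.invwishart_sigma_prior())
    se = 1 / math.sqrt(ctx.jp_hat)
    grid = np.linspace(max(-0.99, ctx.psi_hat - 8 * se),
                       min(0.9985, ctx.psi_hat + 8 * se), 201)
    res = fb.evalue_tailarea(ctx, fb.Hypothesis(0.9), grid=grid)
    assert 0.0 < res.ev < 1.0
    flat = fb.evalue_tailarea(fb.make_context(model, data),
                              fb.Hypothesis(0.9), grid=grid)
    assert 0.0 < flat.ev < 1.0
    assert res.ev != pytest.approx(flat.ev, abs=1e-3)  # the prior matters


def test_jeffreys_prior_builder(flat_exp_data):
    model = fb.ExponentialScale()
    prior = fb.tailarea.jeffreys_prior(model, flat_exp_data)
    # i(θ) = n/θ² so the prior callable is ∝ 1/θ
    ratio = prior(1.0, np.empty(0)) / prior(2.0, np.empty(0))
    assert ratio == pytest.approx(2.0, rel=1e-9)
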