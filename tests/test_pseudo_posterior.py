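"""Pseudo-posterior grids, HPD sets, ABC sampling and KDE modes."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import simpson

import fbstev as fb


def test_mode_matches_bias_reduced_estimator(flat_exp_data):
    """The defining property of the median matching prior: MAP = ψ̃."""
    model = fb.ExponentialScale()
    grid = fb.build_pseudo_posterior(model, flat_exp_data, prior_kind="median")
    n, ybar = 10, 2.0
    assert grid.mode == pytest.approx(n * ybar / (n - 1 / 3), abs=1e-6)
    assert np.trapezoid(grid.density, grid.psi) == pytest.approx(1.0, abs=1e-6)
    # Simpson cross-check of the normalization
    assert simpson(grid.density, x=grid.psi) == pytest.approx(1.0, abs=1e-5)
    assert grid.cdf[0] == 0.0 and grid.cdf[-1] == pytest.approx(1.0)


def test_normal_mean_mode_near_ybar(normal_mean_data):
    """Symmetry makes the profile correction ≈ 0, so the MAP ≈ ȳ.

    The adjustment is bootstrap-estimated, so the check allows its Monte
    Carlo noise (≈ √(κ2/R)/jp per evaluation).
    """
    model, data = normal_mean_data
    grid = fb.build_pseudo_posterior(model, data, prior_kind="median",
                                     replicates=1500, seed=4,
                                     grid_config=fb.GridConfig(
                                         points=301, profile_cache_points=13))
    ybar = float(np.mean(data.y))
    assert grid.mode == pytest.approx(ybar, abs=0.03)


def test_flat_posterior_improper_on_allpositive_sample(allpositive_skewnorm_data):
    model = fb.SkewNormalShape()
    with pytest.raises(fb.ImproperPosteriorError) as err:
        fb.build_pseudo_posterior(model, allpositive_skewnorm_data,
                                  prior_kind="flat",
                                  grid_config=fb.GridConfig(points=301,
                                                            max_expansions=3))
    assert err.value.direction == 1
    grid = fb.build_pseudo_posterior(model, allpositive_skewnorm_data,
                                     prior_kind="median",
                                     grid_config=fb.GridConfig(points=301))
    assert np.isfinite(grid.mode) and grid.mode > 0


def test_quadratic_form_normal_known_variance():
    """tp = n(ȳ−ψ)/σ², jp = n/σ²: the quadratic form is the exact posterior."""
    model = fb.NormalMeanKnownVariance(1.0)
    data = model.simulate([0.0], 25, np.random.default_rng(1))
    grid = fb.quadratic_pseudo_posterior(model, data)
    ybar = float(np.mean(data.y))
    exact = stats.norm.pdf(grid.psi, ybar, 1 / math.sqrt(25))
    assert np.max(np.abs(grid.density - exact)) < 1e-6
    assert grid.mode == pytest.approx(ybar, abs=1e-6)


def test_quadratic_mode_matches_estimating_root(flat_exp_data):
    model = fb.ExponentialScale()
    grid = fb.quadratic_pseudo_posterior(model, flat_exp_data)
    assert grid.mode == pytest.approx(60 / 29, abs=2 * (grid.psi[1] - grid.psi[0]))


def test_quadratic_approaches_full_posterior():
    """Sup-norm distance between Eq-14 and Eq-15 densities shrinks with n."""
    diffs = []
    for n in (20, 50, 200):
        model = fb.ExponentialScale()
        data = model.simulate([1.0], n, np.random.default_rng(21))
        full = fb.build_pseudo_posterior(model, data, prior_kind="median")
        quad = fb.quadratic_pseudo_posterior(model, data)
        common = np.linspace(max(full.psi[0], quad.psi[0]),
                             min(full.psi[-1], quad.psi[-1]), 801)
        diffs.append(np.max(np.abs(full.density_at(common)
                                   - quad.density_at(common)))
                     / np.max(full.density_at(common)))
    assert diffs[0] > diffs[1] > diffs[2]


def test_hpd_standard_normal(std_normal_grid):
    res = fb.hpd_interval(std_normal_grid, 0.95)
    assert not res.multimodal
    lo, hi = res
    assert lo == pytest.approx(-1.960, abs=0.005)
    assert hi == pytest.approx(1.960, abs=0.005)
    wide = fb.hpd_interval(std_normal_grid, 0.9999)
    assert wide.lower < -3.8 and wide.upper > 3.8


def test_hpd_multimodal_union():
    x = np.linspace(-8, 12, 4001)
    logd = np.log(0.6 * stats.norm.pdf(x, 0, 1) + 0.4 * stats.norm.pdf(x, 6, 1))
    grid = fb.PosteriorGrid.from_log_density(x, logd)
    res = fb.hpd_interval(grid, 0.9)
    assert res.multimodal
    assert len(res.intervals) == 2


def test_hpd_exp_transform_contains_exp_mode(flat_exp_data):
    model = fb.ExponentialScale()
    tlog = fb.TransformedScalarModel(model, math.log, math.exp,
                                     (-np.inf, np.inf))
    grid = fb.build_pseudo_posterior(tlog, flat_exp_data, prior_kind="median")
    res = fb.hpd_interval(grid, 0.95)
    base = fb.build_pseudo_posterior(model, flat_exp_data, prior_kind="median")
    assert res.lower < math.log(base.mode) < res.upper


def test_abc_bookkeeping():
    model = fb.SkewNormalShape()
    data = model.simulate([3.0], 20, np.random.default_rng(2))
    sampler = fb.grid_prior_sampler(lambda g: np.zeros_like(g), (-2, 10))
    full = fb.abc_posterior(model, sampler, data, n_draws=500,
                            accept_fraction=1.0, seed=3)
    assert full.accepted.sum() == 500
    part = fb.abc_posterior(model, sampler, data, n_draws=2000,
                            accept_fraction=0.05, seed=3)
    assert part.accepted.sum() == round(0.05 * 2000)
    assert np.all(part.distances[part.accepted]
                  <= part.acceptance_threshold + 1e-12)
    again = fb.abc_posterior(model, sampler, data, n_draws=2000,
                             accept_fraction=0.05, seed=3)
    assert np.array_equal(part.accepted_draws, again.accepted_draws)


def test_abc_conjugate_oracle():
    """Normal mean, flat prior: ABC mean ≈ ȳ as the tolerance tightens."""
    model = fb.NormalMeanKnownVariance(1.0)
    data = model.simulate([0.0], 25, np.random.default_rng(3))
    sampler = fb.grid_prior_sampler(lambda g: np.zeros_like(g), (-3, 3))
    abc = fb.abc_posterior(model, sampler, data, n_draws=60000,
                           accept_fraction=0.01, seed=5)
    acc = abc.accepted_draws
    ybar = float(np.mean(data.y))
    se = float(np.std(acc) / math.sqrt(acc.size))
    # allow the residual ABC tolerance bias on top of Monte Carlo error
    assert abs(float(np.mean(acc)) - ybar) < 3 * se + 0.02


def test_map_from_samples():
    rng = np.random.default_rng(0)
    mode, multimodal = fb.map_from_samples(rng.normal(5.0, 1.0, 100000))
    # the KDE mode of 1e5 normal draws has sampling SD ≈ 0.06
    assert mode == pytest.approx(5.0, abs=0.2)
    assert not multimodal
    value, flag = fb.map_from_samples(np.full(500, 2.5))
    assert value == 2.5 and not flag
    mix = np.concatenate([rng.normal(0, 1, 7000), rng.normal(6, 1, 3000)])
    mode, multimodal = fb.map_from_samples(mix)
    assert abs(mode) < 0.3  # higher-weight component
    assert multimodal
    with pytest.raises(ValueError):
        fb.map_from_samples(np.arange(50.0))


def test_superlevel_mass_against_closed_form(std_normal_grid):
    dens = std_normal_grid.density
    c = float(stats.norm.pdf(1.0))
    mass, intervals = fb.pseudo_posterior.superlevel_mass(
        std_normal_grid.psi, dens, c)
    assert mass == pytest.approx(stats.norm.cdf(1) - stats.norm.cdf(-1),
                                 abs=1e-5)
    assert len(intervals) == 1
    (lo, hi), = intervals
    assert lo == pytest.approx(-1.0, abs=1e-4)
    assert hi == pytest.approx(1.0, abs=1e-4)
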