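import math

import numpy as np
import pytest

import fbstev as fb


@pytest.fixture(scope="session")
def exp_scale_data():
    """n = 10 exponential draws with mean 2 (plus the all-2.0 toy)."""
    return fb.Dataset.from_values(
        np.random.default_rng(3).exponential(2.0, 10))


@pytest.fixture(scope="session")
def flat_exp_data():
    """ȳ = 2 exactly: closed-form roots are rational."""
    return fb.Dataset.from_values([2.0] * 10)


@pytest.fixture(scope="session")
def skewnorm_data():
    """n = 50 skew-normal draws at shape 3 (mixed signs, finite MLE)."""
    model = fb.SkewNormalShape()
    data = model.simulate([3.0], 50, np.random.default_rng(12))
    assert (data.y < 0).any()
    return data


@pytest.fixture(scope="session")
def allpositive_skewnorm_data():
    return fb.generate_fixture("skewnormal-allpositive", 3)


@pytest.fixture(scope="session")
def separated_logistic():
    data = fb.generate_fixture("logistic-separated", 7)
    model = fb.LogisticRegression(covariates=("nv", "pi", "eh"), interest="nv")
    return model, data


@pytest.fixture(scope="session")
def logistic_regular():
    """Well-behaved logistic data: n = 200, no separation."""
    model = fb.LogisticRegression(covariates=("nv", "pi", "eh"), interest="nv")
    data = model.simulate(np.array([0.3, 0.8, -0.5, 0.2]), 200,
                          np.random.default_rng(0))
    return model, data


@pytest.fixture(scope="session")
def normal_mean_data():
    model = fb.NormalMeanVariance()
    data = model.simulate([1.0, 2.0], 30, np.random.default_rng(2))
    return model, data


@pytest.fixture(scope="session")
def std_normal_grid():
    """Dense exact standard-normal density grid."""
    x = np.linspace(-8.5, 8.5, 8001)
    return fb.PosteriorGrid.from_log_density(x, -0.5 * x ** 2)
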