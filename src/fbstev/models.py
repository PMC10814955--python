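"""Parametric model zoo.

Each model exposes the likelihood quantities the inference machinery needs:
log-likelihood, score, observed/expected information, simulation, and (where
available in closed form or by quadrature) the per-observation cumulants of
the score that feed the median and mean (Firth) score modifications.

Supported families
------------------
* canonical one-parameter exponential families (exponential rate, Poisson
  log-mean) built from the cumulant function K and its derivatives,
* the exponential scale model,
* the N(0, θ) variance model,
* the normal model with mean of interest and variance nuisance,
* the skew-normal shape model f(y; θ) = 2 φ(y) Φ(yθ),
* logistic regression,
* bivariate (two response replicates per unit) linear regression with
  equicorrelated normal errors, parameterized as (β0, β1, β2, σ², ρ).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import log_ndtr

from . import _numdiff

__all__ = [
    "Dataset",
    "ParametricModel",
    "ExpFamilyCanonical",
    "exponential_rate_model",
    "poisson_logmean_model",
    "ExponentialScale",
    "NormalVariance",
    "NormalMeanKnownVariance",
    "NormalMeanVariance",
    "SkewNormalShape",
    "LogisticRegression",
    "BivariateRegression",
    "skewnorm_score_expectations",
    "detect_monotone_likelihood",
    "mills_log_ratio",
]


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------

@dataclasses.dataclass
class Dataset:
    """Tabular data with a designated response and covariate columns."""

    frame: pd.DataFrame
    response: str | tuple[str, ...] = "y"
    covariates: tuple[str, ...] = ()
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frame) < 1:
            raise ValueError("dataset must contain at least one observation")
        if self.frame.isna().any().any():
            raise ValueError("dataset contains missing values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        if isinstance(self.response, tuple):
            return self.frame[list(self.response)].to_numpy(dtype=float)
        return self.frame[self.response].to_numpy(dtype=float)

    def design(self, add_intercept: bool = True) -> np.ndarray:
        X = self.frame[list(self.covariates)].to_numpy(dtype=float)
        if add_intercept:
            X = np.column_stack([np.ones(len(self.frame)), X])
        return X

    @classmethod
    def from_values(cls, values: Sequence[float], **kwargs) -> "Dataset":
        return cls(pd.DataFrame({"y": np.asarray(values, dtype=float)}), **kwargs)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, response: str = "y",
                 covariates: Optional[Sequence[str]] = None) -> "Dataset":
        frame = pd.read_csv(path)
        if covariates is None:
            covariates = tuple(c for c in frame.columns if c != response)
        return cls(frame, response=response, covariates=tuple(covariates),
                   provenance={"kind": "file", "path": str(path)})


# --------------------------------------------------------------------------
# base class
# --------------------------------------------------------------------------

class ParametricModel:
    """Base class: numeric fall-backs for all derivative quantities."""

    family: str = "generic"
    param_names: tuple[str, ...] = ("theta",)
    interest_index: int = 0
    #: open-interval support per parameter
    support: tuple[tuple[float, float], ...] = ((-np.inf, np.inf),)
    simulable: bool = False
    closed_form_information: bool = False

    @property
    def dim(self) -> int:
        return len(self.param_names)

    # -- validation -------------------------------------------------------
    def _check_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.size != self.dim:
            raise ValueError(
                f"{self.family}: expected {self.dim} parameter(s), got {theta.size}")
        for value, (lo, hi) in zip(theta, self.support):
            if not (lo < value < hi):
                raise ValueError(
                    f"{self.family}: parameter {value} outside open support ({lo}, {hi})")
        return theta

    # -- likelihood quantities --------------------------------------------
    def loglik_obs(self, theta, data: Dataset) -> np.ndarray:
        raise NotImplementedError

    def loglik(self, theta, data: Dataset) -> float:
        theta = self._check_theta(theta)
        return float(np.sum(self.loglik_obs(theta, data)))

    def score(self, theta, data: Dataset) -> np.ndarray:
        theta = self._check_theta(theta)
        return _numdiff.gradient(lambda t: self.loglik(t, data), theta)

    def observed_info(self, theta, data: Dataset) -> np.ndarray:
        """Negative Hessian of the log-likelihood (matrix, even for d=1)."""
        theta = self._check_theta(theta)
        return -_numdiff.hessian(lambda t: self.loglik(t, data), theta)

    def expected_info(self, theta, data: Optional[Dataset] = None,
                      n: Optional[int] = None) -> np.ndarray:
        """Fisher information for n observations (matrix)."""
        raise NotImplementedError

    # -- simulation --------------------------------------------------------
    def simulate(self, theta, n: int, rng: np.random.Generator) -> Dataset:
        raise NotImplementedError(f"{self.family} is not simulable")

    def simulate_response(self, theta, data: Dataset,
                          rng: np.random.Generator) -> Dataset:
        """New responses with the covariate structure of ``data`` (iid default)."""
        return self.simulate(theta, len(data), rng)

    def simulate_matrix(self, thetas: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
        """(len(thetas), n) matrix of samples, one row per parameter draw.

        Scalar i.i.d. models override this with a vectorized path; the
        generic fallback loops over :meth:`simulate`.
        """
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        out = np.empty((thetas.size, n))
        for i, th in enumerate(thetas):
            out[i] = self.simulate([th], n, rng).y
        return out

    def score_rowwise(self, theta: float, mat: np.ndarray) -> np.ndarray:
        """Per-observation score contributions for a matrix of samples.

        Scalar i.i.d. models only; rows are independent samples.  Used by
        estimating-function ABC summaries.  The generic fallback loops.
        """
        mat = np.atleast_2d(mat)
        out = np.empty_like(mat)
        for i, row in enumerate(mat):
            d = Dataset.from_values(row)
            # distribute the total score evenly: adequate for summaries that
            # only use the row mean
            out[i] = float(self.score([theta], d)[0]) / mat.shape[1]
        return out

    # -- hooks used by the corrections machinery ---------------------------
    def initial_guess(self, data: Dataset) -> np.ndarray:
        return np.zeros(self.dim)

    def score_cumulants_per_obs(self, theta) -> Optional[tuple[float, float]]:
        """(κ2, κ3) of the per-observation score, scalar models only."""
        return None

    def firth_cross_expectation_per_obs(self, theta) -> Optional[float]:
        """E(ℓθθ ℓθ) per observation, scalar models only."""
        return None

    def constrained_nuisance(self, psi: float, data: Dataset) -> Optional[np.ndarray]:
        """Closed-form λ̂ψ where available; None triggers numeric profiling."""
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} family={self.family!r} params={self.param_names}>"


def _as_matrix(x) -> np.ndarray:
    return np.atleast_2d(np.asarray(x, dtype=float))


# --------------------------------------------------------------------------
# canonical exponential families
# --------------------------------------------------------------------------

class ExpFamilyCanonical(ParametricModel):
    """One-parameter exponential family in canonical form.

    f(y; θ) = exp{θ a(y) − K(θ)} b(y).  The score is Σ a(yᵢ) − n Kθ(θ), the
    information n Kθθ(θ) and the third score cumulant n Kθθθ(θ), so the
    median and Firth adjustments are available in closed form.
    """

    family = "exp-family-canonical"
    simulable = True
    closed_form_information = True

    def __init__(self, K, dK, d2K, d3K, suff, log_carrier, sampler,
                 support=((-np.inf, np.inf),), name="exp-family-canonical",
                 param_names=("theta",)):
        self.K, self.dK, self.d2K, self.d3K = K, dK, d2K, d3K
        self.suff = suff
        self.log_carrier = log_carrier
        self._sampler = sampler
        self.support = tuple(support)
        self.family = name
        self.param_names = tuple(param_names)

    def loglik_obs(self, theta, data):
        th = self._check_theta(theta)[0]
        y = data.y
        return th * self.suff(y) - self.K(th) + self.log_carrier(y)

    def score(self, theta, data):
        th = self._check_theta(theta)[0]
        return np.array([float(np.sum(self.suff(data.y))) - len(data) * self.dK(th)])

    def observed_info(self, theta, data):
        th = self._check_theta(theta)[0]
        return np.array([[len(data) * self.d2K(th)]])

    def expected_info(self, theta, data=None, n=None):
        th = self._check_theta(theta)[0]
        n = len(data) if n is None else n
        return np.array([[n * self.d2K(th)]])

    def simulate(self, theta, n, rng):
        th = self._check_theta(theta)[0]
        y = self._sampler(th, n, rng)
        return Dataset.from_values(y, provenance={"kind": "synthetic",
                                                  "generator": self.family})

    def score_cumulants_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        return self.d2K(th), self.d3K(th)

    def firth_cross_expectation_per_obs(self, theta):
        # ℓθθ is non-random in canonical form, so E(ℓθθ ℓθ) = −Kθθ E(ℓθ) = 0.
        return 0.0

    def initial_guess(self, data):
        # moment estimate: solve Kθ(θ) = mean a(y) by bracketing; the
        # equation can be unsolvable at the natural-parameter boundary
        # (e.g. all-zero Poisson counts), in which case a finite interior
        # point is returned and the solver's own bracketing takes over
        target = float(np.mean(self.suff(data.y)))
        lo, hi = self.support[0]

        def f(t: float) -> float:
            try:
                return self.dK(t) - target
            except OverflowError:
                return math.inf if t > 0 else -math.inf

        a = max(lo + 1e-8, -1.0) if np.isfinite(lo) else -1.0
        b = min(hi - 1e-8, 1.0) if np.isfinite(hi) else 1.0
        for _ in range(40):
            if f(a) * f(b) <= 0:
                return np.array([optimize.brentq(f, a, b)])
            width = min(b - a, 50.0)
            a = max(lo + (a - lo) / 2 if np.isfinite(lo) else a - width, lo + 1e-12)
            b = min(hi - (hi - b) / 2 if np.isfinite(hi) else b + width, hi - 1e-12)
        best = a if abs(f(a)) < abs(f(b)) else b
        lo_c = lo + 1e-8 if np.isfinite(lo) else -50.0
        hi_c = hi - 1e-8 if np.isfinite(hi) else 50.0
        return np.array([min(max(best, lo_c), hi_c)])


def exponential_rate_model() -> ExpFamilyCanonical:
    """Exponential distribution with canonical (rate) parameter θ > 0.

    a(y) = −y, K(θ) = −log θ.
    """
    return ExpFamilyCanonical(
        K=lambda t: -math.log(t),
        dK=lambda t: -1.0 / t,
        d2K=lambda t: 1.0 / t ** 2,
        d3K=lambda t: -2.0 / t ** 3,
        suff=lambda y: -y,
        log_carrier=lambda y: np.zeros_like(y),
        sampler=lambda t, n, rng: rng.exponential(scale=1.0 / t, size=n),
        support=((0.0, np.inf),),
        name="exponential-rate",
        param_names=("rate",),
    )


def gamma_rate_model(shape: float = 3.0) -> ExpFamilyCanonical:
    """Gamma with known shape and canonical (rate) parameter θ > 0.

    a(y) = −y, K(θ) = −shape · log θ.
    """
    import math as _math

    def log_carrier(y):
        y = np.atleast_1d(y)
        return (shape - 1.0) * np.log(y) - _math.lgamma(shape)

    return ExpFamilyCanonical(
        K=lambda t: -shape * math.log(t),
        dK=lambda t: -shape / t,
        d2K=lambda t: shape / t ** 2,
        d3K=lambda t: -2.0 * shape / t ** 3,
        suff=lambda y: -y,
        log_carrier=log_carrier,
        sampler=lambda t, n, rng: rng.gamma(shape, scale=1.0 / t, size=n),
        support=((0.0, np.inf),),
        name="gamma-rate",
        param_names=("rate",),
    )


def poisson_logmean_model() -> ExpFamilyCanonical:
    """Poisson with canonical parameter θ = log mean.  K(θ) = exp(θ)."""
    return ExpFamilyCanonical(
        K=math.exp, dK=math.exp, d2K=math.exp, d3K=math.exp,
        suff=lambda y: y,
        log_carrier=lambda y: -np.array([math.lgamma(v + 1.0) for v in np.atleast_1d(y)]),
        sampler=lambda t, n, rng: rng.poisson(lam=math.exp(t), size=n).astype(float),
        support=((-np.inf, np.inf),),
        name="poisson-logmean",
        param_names=("logmean",),
    )


# --------------------------------------------------------------------------
# scale / variance models
# --------------------------------------------------------------------------

class ExponentialScale(ParametricModel):
    """Exponential distribution parameterized by the scale (mean) θ > 0."""

    family = "exponential-scale"
    param_names = ("scale",)
    support = ((0.0, np.inf),)
    simulable = True
    closed_form_information = True

    def loglik_obs(self, theta, data):
        th = self._check_theta(theta)[0]
        return -math.log(th) - data.y / th

    def score(self, theta, data):
        th = self._check_theta(theta)[0]
        n = len(data)
        return np.array([-n / th + float(np.sum(data.y)) / th ** 2])

    def observed_info(self, theta, data):
        th = self._check_theta(theta)[0]
        n = len(data)
        return np.array([[-n / th ** 2 + 2.0 * float(np.sum(data.y)) / th ** 3]])

    def expected_info(self, theta, data=None, n=None):
        th = self._check_theta(theta)[0]
        n = len(data) if n is None else n
        return np.array([[n / th ** 2]])

    def simulate(self, theta, n, rng):
        th = self._check_theta(theta)[0]
        return Dataset.from_values(rng.exponential(scale=th, size=n),
                                   provenance={"kind": "synthetic",
                                               "generator": self.family})

    def score_cumulants_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        # per-obs score (y − θ)/θ²; y ~ Exp(mean θ) has central moments θ², 2θ³
        return 1.0 / th ** 2, 2.0 / th ** 3

    def firth_cross_expectation_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        # ℓθθ = 1/θ² − 2y/θ³, ℓθ = (y−θ)/θ²; E(ℓθθ ℓθ) = −2 Var(y)/θ⁵ = −2/θ³
        return -2.0 / th ** 3

    def initial_guess(self, data):
        return np.array([float(np.mean(data.y))])


class NormalVariance(ParametricModel):
    """N(0, θ): variance parameter, zero known mean."""

    family = "normal-variance"
    param_names = ("variance",)
    support = ((0.0, np.inf),)
    simulable = True
    closed_form_information = True

    def loglik_obs(self, theta, data):
        th = self._check_theta(theta)[0]
        return -0.5 * math.log(2.0 * math.pi * th) - data.y ** 2 / (2.0 * th)

    def score(self, theta, data):
        th = self._check_theta(theta)[0]
        n = len(data)
        return np.array([-0.5 * n / th + float(np.sum(data.y ** 2)) / (2.0 * th ** 2)])

    def observed_info(self, theta, data):
        th = self._check_theta(theta)[0]
        return np.array([[-0.5 * len(data) / th ** 2
                          + float(np.sum(data.y ** 2)) / th ** 3]])

    def expected_info(self, theta, data=None, n=None):
        th = self._check_theta(theta)[0]
        n = len(data) if n is None else n
        return np.array([[0.5 * n / th ** 2]])

    def simulate(self, theta, n, rng):
        th = self._check_theta(theta)[0]
        return Dataset.from_values(rng.normal(scale=math.sqrt(th), size=n),
                                   provenance={"kind": "synthetic",
                                               "generator": self.family})

    def score_cumulants_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        # score per obs (y² − θ)/(2θ²); y²/θ ~ χ²₁ with cumulants 1, 2, 8
        return 0.5 / th ** 2, 1.0 / th ** 3

    def firth_cross_expectation_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        # ℓθθ = 1/(2θ²) − y²/θ³; Cov(−y²/θ³, y²/(2θ²)) = −Var(y²)/(2θ⁵) = −1/θ³
        return -1.0 / th ** 3

    def initial_guess(self, data):
        return np.array([float(np.mean(data.y ** 2))])


class NormalMeanKnownVariance(ParametricModel):
    """N(ψ, σ²) with σ² known — the exactness benchmark for the tail-area path."""

    family = "normal-mean-knownvar"
    param_names = ("mean",)
    simulable = True
    closed_form_information = True

    def __init__(self, sigma2: float = 1.0):
        self.sigma2 = float(sigma2)

    def loglik_obs(self, theta, data):
        mu = self._check_theta(theta)[0]
        return -0.5 * math.log(2.0 * math.pi * self.sigma2) \
            - (data.y - mu) ** 2 / (2.0 * self.sigma2)

    def score(self, theta, data):
        mu = self._check_theta(theta)[0]
        return np.array([float(np.sum(data.y - mu)) / self.sigma2])

    def observed_info(self, theta, data):
        return np.array([[len(data) / self.sigma2]])

    def expected_info(self, theta, data=None, n=None):
        n = len(data) if n is None else n
        return np.array([[n / self.sigma2]])

    def simulate(self, theta, n, rng):
        mu = self._check_theta(theta)[0]
        return Dataset.from_values(rng.normal(mu, math.sqrt(self.sigma2), size=n),
                                   provenance={"kind": "synthetic",
                                               "generator": self.family})

    def score_cumulants_per_obs(self, theta):
        return 1.0 / self.sigma2, 0.0

    def firth_cross_expectation_per_obs(self, theta):
        return 0.0

    def initial_guess(self, data):
        return np.array([float(np.mean(data.y))])


class NormalMeanVariance(ParametricModel):
    """N(ψ, λ) with mean of interest and variance nuisance."""

    family = "normal-mean-variance"
    param_names = ("mean", "variance")
    interest_index = 0
    support = ((-np.inf, np.inf), (0.0, np.inf))
    simulable = True
    closed_form_information = True

    def loglik_obs(self, theta, data):
        mu, v = self._check_theta(theta)
        return -0.5 * np.log(2.0 * np.pi * v) - (data.y - mu) ** 2 / (2.0 * v)

    def score(self, theta, data):
        mu, v = self._check_theta(theta)
        r = data.y - mu
        return np.array([float(np.sum(r)) / v,
                         -0.5 * len(data) / v + float(np.sum(r ** 2)) / (2.0 * v ** 2)])

    def observed_info(self, theta, data):
        mu, v = self._check_theta(theta)
        r = data.y - mu
        n = len(data)
        sr = float(np.sum(r))
        sr2 = float(np.sum(r ** 2))
        return np.array([[n / v, sr / v ** 2],
                         [sr / v ** 2, -0.5 * n / v ** 2 + sr2 / v ** 3]])

    def expected_info(self, theta, data=None, n=None):
        mu, v = self._check_theta(theta)
        n = len(data) if n is None else n
        return np.diag([n / v, 0.5 * n / v ** 2])

    def simulate(self, theta, n, rng):
        mu, v = self._check_theta(theta)
        return Dataset.from_values(rng.normal(mu, math.sqrt(v), size=n),
                                   provenance={"kind": "synthetic",
                                               "generator": self.family})

    def constrained_nuisance(self, psi, data):
        return np.array([float(np.mean((data.y - psi) ** 2))])

    def initial_guess(self, data):
        return np.array([float(np.mean(data.y)), float(np.var(data.y)) + 1e-12])


# --------------------------------------------------------------------------
# skew-normal shape model
# --------------------------------------------------------------------------

def mills_log_ratio(u: np.ndarray) -> np.ndarray:
    """log{φ(u)/Φ(u)}, stable for u far in the lower tail via log_ndtr."""
    u = np.asarray(u, dtype=float)
    return stats.norm.logpdf(u) - log_ndtr(u)


def _zeta(u: np.ndarray) -> np.ndarray:
    """Inverse Mills ratio φ(u)/Φ(u)."""
    return np.exp(mills_log_ratio(u))


def _skewnorm_expectation(theta: float, p: int, k: int) -> float:
    """E[ y^p ζ(yθ)^k ] under the skew-normal density 2 φ(y) Φ(yθ).

    Evaluated in log space so that the Φ(yθ)^(k−1) in the denominator never
    underflows, with the integration range split at 0 where the integrand
    kinks for large |θ|.
    """
    th = float(theta)

    def integrand(y: float) -> float:
        u = y * th
        logval = (math.log(2.0) + stats.norm.logpdf(y)
                  + k * stats.norm.logpdf(u) - (k - 1) * log_ndtr(u))
        return y ** p * math.exp(logval)

    # the integrand kinks at 0 and, for large |θ|, concentrates on a 1/|θ|
    # scale on the side where yθ < 0 — split accordingly
    s = max(abs(th), 1.0)
    cuts = (-np.inf, -20.0 / s, 0.0, 20.0 / s, np.inf)
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        val, err = integrate.quad(integrand, a, b, epsabs=1e-13, epsrel=1e-10,
                                  limit=300)
        if not np.isfinite(val):
            raise ArithmeticError(
                f"skew-normal quadrature failed on ({a}, {b}): value {val}, err {err}")
        total += val
    return total


def skewnorm_score_expectations(theta: float, order: int) -> float:
    """E[(y φ(yθ)/Φ(yθ))^order] under 2 φ(y) Φ(yθ), order ∈ {2, 3}.

    These are the per-observation score moments that drive the median
    matching prior for the shape parameter; they have no closed form except
    at θ = 0 (where the order-2 value is 2/π and the order-3 value vanishes
    by symmetry).
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    return _skewnorm_expectation(theta, order, order)


class SkewNormalShape(ParametricModel):
    """Skew-normal with shape θ: f(y; θ) = 2 φ(y) Φ(yθ), location 0, scale 1."""

    family = "skew-normal-shape"
    param_names = ("shape",)
    simulable = True

    def loglik_obs(self, theta, data):
        th = self._check_theta(theta)[0]
        y = data.y
        return math.log(2.0) + stats.norm.logpdf(y) + log_ndtr(y * th)

    def score(self, theta, data):
        th = self._check_theta(theta)[0]
        y = data.y
        return np.array([float(np.sum(y * _zeta(y * th)))])

    def observed_info(self, theta, data):
        th = self._check_theta(theta)[0]
        y = data.y
        u = y * th
        z = _zeta(u)
        # d²/dθ² log Φ(yθ) = y² ζ'(yθ) with ζ'(u) = −u ζ(u) − ζ(u)²
        return np.array([[float(np.sum(y ** 2 * (u * z + z ** 2)))]])

    def expected_info(self, theta, data=None, n=None):
        th = self._check_theta(theta)[0]
        n = len(data) if n is None else n
        return np.array([[n * skewnorm_score_expectations(th, 2)]])

    def simulate(self, theta, n, rng):
        th = self._check_theta(theta)[0]
        # additive representation: y = (δ|z0| + sqrt(1−δ²) z1), δ = θ/√(1+θ²)
        delta = th / math.sqrt(1.0 + th * th)
        z0 = np.abs(rng.standard_normal(n))
        z1 = rng.standard_normal(n)
        y = delta * z0 + math.sqrt(1.0 - delta * delta) * z1
        return Dataset.from_values(y, provenance={"kind": "synthetic",
                                                  "generator": self.family})

    def simulate_matrix(self, thetas, n, rng):
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        delta = (thetas / np.sqrt(1.0 + thetas ** 2))[:, None]
        z0 = np.abs(rng.standard_normal((thetas.size, n)))
        z1 = rng.standard_normal((thetas.size, n))
        return delta * z0 + np.sqrt(1.0 - delta ** 2) * z1

    def score_rowwise(self, theta, mat):
        mat = np.atleast_2d(mat)
        return mat * _zeta(mat * float(theta))

    def score_cumulants_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        return (skewnorm_score_expectations(th, 2),
                skewnorm_score_expectations(th, 3))

    def firth_cross_expectation_per_obs(self, theta):
        th = self._check_theta(theta)[0]
        # ℓθθ ℓθ = y³ ζ'(yθ) ζ(yθ) = −θ y⁴ ζ² − y³ ζ³
        return (-th * _skewnorm_expectation(th, 4, 2)
                - _skewnorm_expectation(th, 3, 3))

    def initial_guess(self, data):
        g1 = float(stats.skew(data.y))
        g1 = float(np.clip(g1, -0.9, 0.9))  # attainable skewness < 0.9953
        c = (2.0 * abs(g1) / (4.0 - math.pi)) ** (1.0 / 3.0)
        delta = math.copysign(min(c / math.sqrt(2.0 / math.pi * (1.0 + c * c)), 0.99),
                              g1)
        return np.array([delta / math.sqrt(max(1.0 - delta * delta, 1e-6))])


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

class LogisticRegression(ParametricModel):
    """Binary logistic regression with intercept.

    θ is the coefficient vector aligned with ("intercept", *covariates).
    Simulation keeps the covariates of a template dataset and redraws the
    binary responses (the parametric-bootstrap convention for regression).
    """

    family = "logistic-regression"
    simulable = True
    closed_form_information = True

    def __init__(self, covariates: Sequence[str], interest: Optional[str] = None,
                 response: str = "y"):
        self.covariates = tuple(covariates)
        self.response = response
        self.param_names = ("intercept",) + self.covariates
        self.support = tuple(((-np.inf, np.inf),) * len(self.param_names))
        self.interest_index = (self.param_names.index(interest)
                               if interest is not None else 1 if self.covariates else 0)

    def _design(self, data: Dataset) -> np.ndarray:
        X = data.frame[list(self.covariates)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(data)), X])

    def loglik_obs(self, theta, data):
        beta = self._check_theta(theta)
        eta = self._design(data) @ beta
        y = data.frame[self.response].to_numpy(dtype=float)
        return y * eta - np.logaddexp(0.0, eta)

    def score(self, theta, data):
        beta = self._check_theta(theta)
        X = self._design(data)
        y = data.frame[self.response].to_numpy(dtype=float)
        p = _expit(X @ beta)
        return X.T @ (y - p)

    def observed_info(self, theta, data):
        return self.expected_info(theta, data)

    def expected_info(self, theta, data=None, n=None):
        if data is None:
            raise ValueError("logistic information requires the design matrix")
        beta = self._check_theta(theta)
        X = self._design(data)
        p = _expit(X @ beta)
        W = p * (1.0 - p)
        return X.T @ (X * W[:, None])

    def simulate_response(self, theta, data, rng):
        beta = self._check_theta(theta)
        X = self._design(data)
        p = _expit(X @ beta)
        frame = data.frame.copy()
        frame[self.response] = (rng.random(len(data)) < p).astype(float)
        return Dataset(frame, response=self.response, covariates=self.covariates,
                       provenance={"kind": "synthetic", "generator": self.family})

    def simulate(self, theta, n, rng):
        frame = pd.DataFrame({c: rng.standard_normal(n) for c in self.covariates})
        frame[self.response] = 0.0
        template = Dataset(frame, response=self.response, covariates=self.covariates)
        return self.simulate_response(theta, template, rng)

    def initial_guess(self, data):
        return np.zeros(self.dim)


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit
    return expit(x)


# --------------------------------------------------------------------------
# bivariate regression with equicorrelated errors
# --------------------------------------------------------------------------

class BivariateRegression(ParametricModel):
    """Two response replicates per unit sharing one linear predictor.

    y_ij = β0 + β1 x_i1 + β2 x_i2 + ε_ij, j = 1, 2, with
    ε_i ~ N2(0, σ² [[1, ρ], [ρ, 1]]).  The interest parameter defaults to ρ.
    Dataset columns: y1, y2, x1, x2.
    """

    family = "bivariate-regression"
    param_names = ("beta0", "beta1", "beta2", "sigma2", "rho")
    interest_index = 4
    support = ((-np.inf, np.inf),) * 3 + ((0.0, np.inf), (-1.0, 1.0))
    simulable = True

    response = ("y1", "y2")
    covariates = ("x1", "x2")

    def _parts(self, theta, data):
        b0, b1, b2, s2, rho = self._check_theta(theta)
        f = data.frame
        eta = b0 + b1 * f["x1"].to_numpy(float) + b2 * f["x2"].to_numpy(float)
        e1 = f["y1"].to_numpy(float) - eta
        e2 = f["y2"].to_numpy(float) - eta
        return b0, b1, b2, s2, rho, e1, e2

    def loglik_obs(self, theta, data):
        _, _, _, s2, rho, e1, e2 = self._parts(theta, data)
        q = e1 ** 2 + e2 ** 2 - 2.0 * rho * e1 * e2
        return (-math.log(2.0 * math.pi) - math.log(s2)
                - 0.5 * math.log(1.0 - rho * rho)
                - q / (2.0 * s2 * (1.0 - rho * rho)))

    def score(self, theta, data):
        _, _, _, s2, rho, e1, e2 = self._parts(theta, data)
        f = data.frame
        x1 = f["x1"].to_numpy(float)
        x2 = f["x2"].to_numpy(float)
        n = len(data)
        one_m = 1.0 - rho * rho
        common = (e1 + e2) / (s2 * (1.0 + rho))
        q = e1 ** 2 + e2 ** 2 - 2.0 * rho * e1 * e2
        d_s2 = -n / s2 + float(np.sum(q)) / (2.0 * s2 ** 2 * one_m)
        d_rho = (n * rho / one_m + float(np.sum(e1 * e2)) / (s2 * one_m)
                 - rho * float(np.sum(q)) / (s2 * one_m ** 2))
        return np.array([float(np.sum(common)),
                         float(np.sum(common * x1)),
                         float(np.sum(common * x2)),
                         d_s2, d_rho])

    def observed_info(self, theta, data):
        # differentiate the analytic score: one FD order cheaper and with a
        # smaller step than a full numeric Hessian, which matters close to
        # the |ρ| < 1 boundary
        theta = self._check_theta(theta)
        J = _numdiff.jacobian(lambda t: self.score(t, data), theta)
        return -0.5 * (J + J.T)

    def expected_info(self, theta, data=None, n=None):
        """Observed information at the data, standing in for the expectation.

        The β-block is exactly the Fisher information given the covariates;
        the (σ², ρ)-block differs from its expectation by mean-zero residual
        terms of order n^{-1/2}.
        """
        if data is None:
            raise ValueError("bivariate-regression information requires covariates")
        return self.observed_info(theta, data)

    def simulate_response(self, theta, data, rng):
        b0, b1, b2, s2, rho = self._check_theta(theta)
        f = data.frame
        n = len(data)
        eta = b0 + b1 * f["x1"].to_numpy(float) + b2 * f["x2"].to_numpy(float)
        z = rng.standard_normal((n, 2))
        e1 = z[:, 0]
        e2 = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
        frame = pd.DataFrame({
            "y1": eta + math.sqrt(s2) * e1,
            "y2": eta + math.sqrt(s2) * e2,
            "x1": f["x1"].to_numpy(float),
            "x2": f["x2"].to_numpy(float),
        })
        return Dataset(frame, response=self.response, covariates=self.covariates,
                       provenance={"kind": "synthetic", "generator": self.family})

    def simulate(self, theta, n, rng):
        frame = pd.DataFrame({
            "y1": np.zeros(n), "y2": np.zeros(n),
            "x1": rng.standard_normal(n), "x2": rng.standard_normal(n),
        })
        template = Dataset(frame, response=self.response, covariates=self.covariates)
        return self.simulate_response(theta, template, rng)

    def initial_guess(self, data):
        f = data.frame
        X = np.column_stack([np.ones(len(data)),
                             f["x1"].to_numpy(float), f["x2"].to_numpy(float)])
        ybar = 0.5 * (f["y1"].to_numpy(float) + f["y2"].to_numpy(float))
        beta, *_ = np.linalg.lstsq(X, ybar, rcond=None)
        e1 = f["y1"].to_numpy(float) - X @ beta
        e2 = f["y2"].to_numpy(float) - X @ beta
        s2 = 0.5 * float(np.mean(e1 ** 2) + np.mean(e2 ** 2))
        rho = float(np.clip(np.mean(e1 * e2) / s2, -0.95, 0.95))
        return np.array([*beta, max(s2, 1e-8), rho])


# --------------------------------------------------------------------------
# monotone scalar reparameterization
# --------------------------------------------------------------------------

class TransformedScalarModel(ParametricModel):
    """A scalar model re-expressed in φ = g(θ), g smooth and monotone.

    Likelihood quantities follow by the chain rule with c(φ) = dθ/dφ:
    score_φ = c · score_θ, i_φ = c² i_θ, κ3,φ = c³ κ3,θ and
    E(ℓφφ ℓφ) = c³ E(ℓθθ ℓθ) + c c′ i_θ.  c and c′ are taken by central
    differences of the supplied inverse map.
    """

    def __init__(self, base: ParametricModel, g: Callable[[float], float],
                 g_inv: Callable[[float], float],
                 support: tuple[float, float]):
        if base.dim != 1:
            raise ValueError("TransformedScalarModel wraps scalar models only")
        self.base = base
        self.g = g
        self.g_inv = g_inv
        self.family = f"{base.family}-transformed"
        self.param_names = (f"g({base.param_names[0]})",)
        self.support = (tuple(support),)
        self.simulable = base.simulable
        self.closed_form_information = base.closed_form_information

    def _c(self, phi: float, order: int = 1) -> float:
        return _numdiff.derivative(self.g_inv, phi, order=order)

    def loglik_obs(self, theta, data):
        phi = self._check_theta(theta)[0]
        return self.base.loglik_obs([self.g_inv(phi)], data)

    def score(self, theta, data):
        phi = self._check_theta(theta)[0]
        return self.base.score([self.g_inv(phi)], data) * self._c(phi)

    def expected_info(self, theta, data=None, n=None):
        phi = self._check_theta(theta)[0]
        return self.base.expected_info([self.g_inv(phi)], data=data, n=n) \
            * self._c(phi) ** 2

    def simulate(self, theta, n, rng):
        phi = self._check_theta(theta)[0]
        return self.base.simulate([self.g_inv(phi)], n, rng)

    def score_cumulants_per_obs(self, theta):
        phi = self._check_theta(theta)[0]
        per = self.base.score_cumulants_per_obs([self.g_inv(phi)])
        if per is None:
            return None
        c = self._c(phi)
        return per[0] * c ** 2, per[1] * c ** 3

    def firth_cross_expectation_per_obs(self, theta):
        phi = self._check_theta(theta)[0]
        th = self.g_inv(phi)
        cross = self.base.firth_cross_expectation_per_obs([th])
        if cross is None:
            return None
        c = self._c(phi)
        cprime = self._c(phi, order=2)
        i1 = float(self.base.expected_info([th], n=1)[0, 0])
        return c ** 3 * cross + c * cprime * i1

    def initial_guess(self, data):
        th = float(self.base.initial_guess(data)[0])
        return np.array([self.g(th)])


# --------------------------------------------------------------------------
# monotone-likelihood detection
# --------------------------------------------------------------------------

def detect_monotone_likelihood(model: ParametricModel, data: Dataset,
                               interest_index: Optional[int] = None,
                               max_expansions: int = 25) -> tuple[bool, int]:
    """Detect a monotone (profile) likelihood in the interest parameter.

    Returns ``(flag, direction)`` with direction +1 when the (profile) score
    stays positive over an expanding bracket (estimate drifts to +∞), −1 for
    the opposite drift and 0 when a sign change is found (finite MLE).
    The bracket doubles from one interest-scale unit up to about 10⁶ units
    or the support boundary.
    """
    from . import corrections  # local import: corrections depends on models

    idx = model.interest_index if interest_index is None else interest_index
    lo, hi = model.support[idx]

    if model.dim == 1:
        score_fn = lambda p: float(model.score(np.array([p]), data)[0])
        center = float(model.initial_guess(data)[0])
    else:
        score_fn = lambda p: corrections.profile_score(model, p, data,
                                                       interest_index=idx)
        center = float(model.initial_guess(data)[idx])

    if np.isfinite(lo):
        center = max(center, lo + 1e-6)
    if np.isfinite(hi):
        center = min(center, hi - 1e-6)

    sa = sb = score_fn(center)
    half = 1.0
    for k in range(max_expansions):
        # unbounded side: arithmetic doubling; bounded side: approach the
        # boundary geometrically
        a = (center - half) if not np.isfinite(lo) else lo + (center - lo) / 2.0 ** (k + 1)
        b = (center + half) if not np.isfinite(hi) else hi - (hi - center) / 2.0 ** (k + 1)
        sa, sb = score_fn(a), score_fn(b)
        if sa > 0.0 > sb:
            return False, 0
        half *= 2.0
        if half > 1e6:
            break
    # no sign change: the score keeps the sign it has on the near side of
    # the bracket (the far side may underflow to 0)
    return True, (1 if sa > 0.0 else -1)
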