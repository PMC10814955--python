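"""Scalar pseudo-posteriors, HPD sets and the rejection-ABC sampler.

The pseudo-posterior for a scalar interest parameter ψ is

    log π*(ψ | y) = ℓp(ψ) + ∫ m(ψ, λ̂ψ) dψ + const,

where ℓp is the profile log-likelihood and m the score adjustment of the
chosen prior kind (median matching, Firth/predictive, Jeffreys, or zero for
a flat prior).  The integral of the adjustment is the log matching prior;
its additive constant is immaterial after normalization.  A quadratic
(Rao-score) approximation exp{−tp(ψ)²/(2 jp(ψ))} is also provided.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional

import numpy as np
from scipy import integrate, interpolate, optimize, stats

from . import corrections
from .corrections import DivergenceError, ProfileOptimizationError
from .models import Dataset, LogisticRegression, ParametricModel

__all__ = [
    "GridConfig",
    "PosteriorGrid",
    "HpdResult",
    "AbcSample",
    "ImproperPosteriorError",
    "build_pseudo_posterior",
    "quadratic_pseudo_posterior",
    "hpd_interval",
    "abc_posterior",
    "map_from_samples",
    "superlevel_mass",
    "grid_prior_sampler",
]


class ImproperPosteriorError(RuntimeError):
    """The requested posterior does not normalize (monotone likelihood)."""

    def __init__(self, message: str, direction: int = 0):
        super().__init__(message)
        self.direction = direction


@dataclasses.dataclass
class GridConfig:
    points: int = 801
    span_se: float = 8.0          # grid half-width in SE units
    boundary_tol: float = 1e-4    # max mass in the outermost two cells per side
    max_expansions: int = 6
    correction_subgrid: int = 61  # coarse grid for the (costly) adjustment
    profile_cache_points: int = 41


@dataclasses.dataclass
class PosteriorGrid:
    """Normalized 1-D density on an ordered grid."""

    psi: np.ndarray
    log_density_unnorm: np.ndarray
    density: np.ndarray
    log_norm_const: float
    mode: float
    cdf: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_log_density(cls, psi: np.ndarray, log_unnorm: np.ndarray,
                         mode_refiner: Optional[Callable[[float, float], float]] = None,
                         meta: Optional[dict] = None) -> "PosteriorGrid":
        psi = np.asarray(psi, dtype=float)
        log_unnorm = np.asarray(log_unnorm, dtype=float)
        shift = np.max(log_unnorm)
        dens = np.exp(log_unnorm - shift)
        norm = float(np.trapezoid(dens, psi))
        if not np.isfinite(norm) or norm <= 0:
            raise ImproperPosteriorError("density does not normalize on the grid")
        dens /= norm
        cdf = integrate.cumulative_trapezoid(dens, psi, initial=0.0)
        cdf /= cdf[-1]
        k = int(np.argmax(dens))
        mode = float(psi[k])
        if mode_refiner is not None and 0 < k < len(psi) - 1:
            mode = float(mode_refiner(psi[k - 1], psi[k + 1]))
        return cls(psi=psi, log_density_unnorm=log_unnorm, density=dens,
                   log_norm_const=float(shift + math.log(norm)), mode=mode,
                   cdf=cdf, meta=meta or {})

    def density_at(self, x) -> np.ndarray:
        return np.interp(x, self.psi, self.density)

    def cdf_at(self, x) -> np.ndarray:
        return np.interp(x, self.psi, self.cdf)

    def boundary_mass(self) -> float:
        left = float(np.trapezoid(self.density[:3], self.psi[:3]))
        right = float(np.trapezoid(self.density[-3:], self.psi[-3:]))
        return max(left, right)


@dataclasses.dataclass
class HpdResult:
    intervals: list[tuple[float, float]]
    level: float
    threshold: float
    multimodal: bool

    def __iter__(self):
        lo = min(a for a, _ in self.intervals)
        hi = max(b for _, b in self.intervals)
        return iter((lo, hi))

    @property
    def lower(self) -> float:
        return min(a for a, _ in self.intervals)

    @property
    def upper(self) -> float:
        return max(b for _, b in self.intervals)


@dataclasses.dataclass
class AbcSample:
    draws: np.ndarray
    distances: np.ndarray
    acceptance_threshold: float
    accepted: np.ndarray  # boolean flags
    n_draws: int
    acceptance_fraction: float
    seed: Optional[int]

    @property
    def accepted_draws(self) -> np.ndarray:
        return self.draws[self.accepted]


# --------------------------------------------------------------------------
# superlevel-set mass (shared with the e-value machinery)
# --------------------------------------------------------------------------

def superlevel_mass(x: np.ndarray, dens: np.ndarray, level: float,
                    mass_density: Optional[np.ndarray] = None,
                    ) -> tuple[float, list[tuple[float, float]]]:
    """Mass over {dens > level} by trapezoid with interpolated crossings.

    The set is cut on ``dens``; the integrand is ``mass_density`` (defaults
    to ``dens`` itself).  Separating the two supports parameterization-
    invariant tangential-set masses, where the cut uses the surprise
    function but the mass uses an information-weighted measure.
    """
    x = np.asarray(x, dtype=float)
    dens = np.asarray(dens, dtype=float)
    md = dens if mass_density is None else np.asarray(mass_density, dtype=float)
    mass = 0.0
    intervals: list[tuple[float, float]] = []
    open_start: Optional[float] = None

    def md_at(x0, x1, xc, m0, m1):
        return m0 + (m1 - m0) * (xc - x0) / (x1 - x0)

    for i in range(len(x) - 1):
        x0, x1 = x[i], x[i + 1]
        d0, d1 = dens[i], dens[i + 1]
        m0, m1 = md[i], md[i + 1]
        above0, above1 = d0 > level, d1 > level
        if above0 and above1:
            mass += 0.5 * (m0 + m1) * (x1 - x0)
            if open_start is None:
                open_start = x0
        elif above0 and not above1:
            xc = x0 + (level - d0) / (d1 - d0) * (x1 - x0)
            mass += 0.5 * (m0 + md_at(x0, x1, xc, m0, m1)) * (xc - x0)
            intervals.append((open_start if open_start is not None else x0, xc))
            open_start = None
        elif not above0 and above1:
            xc = x0 + (level - d0) / (d1 - d0) * (x1 - x0)
            mass += 0.5 * (md_at(x0, x1, xc, m0, m1) + m1) * (x1 - xc)
            open_start = xc
    if open_start is not None:
        intervals.append((open_start, x[-1]))
    return mass, intervals


# --------------------------------------------------------------------------
# grid construction
# --------------------------------------------------------------------------

def _center_and_se(model: ParametricModel, data: Dataset, idx: int,
                   prior_kind: str) -> tuple[float, float]:
    if model.dim == 1:
        try:
            mle = float(corrections.full_mle(model, data)[0])
            j = float(model.observed_info([mle], data)[0, 0])
            if j > 0:
                return mle, 1.0 / math.sqrt(j)
        except DivergenceError as err:
            if prior_kind in ("none", "flat"):
                raise ImproperPosteriorError(
                    "flat pseudo-posterior is improper: the likelihood is "
                    f"monotone towards {'+' if err.direction > 0 else '-'}infinity",
                    err.direction) from err
            est = corrections.solve_modified_score(
                model, data, "median" if prior_kind == "median" else "firth")
            return est.value, est.standard_error
        est = corrections.solve_modified_score(model, data, "median")
        return est.value, est.standard_error
    return corrections._interest_center(model, data, idx)


def _correction_spline(model: ParametricModel, data: Dataset, idx: int,
                       prior_kind: str, window: tuple[float, float],
                       cfg: GridConfig, replicates: int, seed: Optional[int]):
    """Interpolant of m(ψ) over the working window, for ∫m and tp.

    Scalar models use a monotone cubic (PCHIP) on a coarse subgrid — the
    adjustment can be steep near a support boundary and PCHIP does not ring.
    Profile adjustments (Monte-Carlo cumulants) use the coarse cubic cache.
    """
    a, b = window
    if prior_kind in ("none", "flat"):
        return interpolate.PchipInterpolator([a, (a + b) / 2, b], [0.0, 0.0, 0.0])
    if model.dim == 1:
        sub = np.linspace(a, b, cfg.correction_subgrid)
        corr = corrections.make_correction(model, prior_kind, data=data, seed=seed)
        vals = np.array([corr(t) for t in sub])
        lo, hi = model.support[idx]
        if np.isinf(lo) and np.isinf(hi):
            # O(h^4) on a support without boundary steepness
            return interpolate.CubicSpline(sub, vals)
        # near a finite boundary the adjustment can be steep (e.g. 1/(3θ));
        # the monotone cubic does not ring there
        return interpolate.PchipInterpolator(sub, vals)
    if prior_kind == "median":
        center = 0.5 * (a + b)
        se = (b - a) / (2.0 * cfg.span_se)
        spline, _ = corrections._profile_correction_cache(
            model, data, idx, "median", center, se, replicates, seed,
            n_grid=cfg.profile_cache_points, span=cfg.span_se)
        return spline
    raise ValueError(f"unsupported prior kind {prior_kind!r} with nuisance "
                     "parameters (use 'median', 'flat', or the penalized "
                     "Jeffreys path for 'firth' in logistic models)")


def _penalized_profile_logpost(model: LogisticRegression, psi: float,
                               data: Dataset, idx: int) -> float:
    """Profile over λ of ℓ(β) + (1/2) log|i(β)| (Jeffreys joint prior).

    Used as the predictive-matching pseudo-posterior in logistic regression,
    where the predictive matching prior coincides with Jeffreys' prior.
    """
    nuis = [i for i in range(model.dim) if i != idx]

    def neg(lam):
        theta = np.empty(model.dim)
        theta[idx] = psi
        theta[nuis] = lam
        info = model.expected_info(theta, data=data)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return np.inf
        return -(model.loglik(theta, data) + 0.5 * logdet)

    start = np.zeros(len(nuis))
    res = optimize.minimize(neg, start, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 500})
    return -float(res.fun)


def build_pseudo_posterior(model: ParametricModel, data: Dataset,
                           interest_index: Optional[int] = None,
                           prior_kind: str = "median",
                           grid_config: Optional[GridConfig] = None,
                           seed: Optional[int] = None,
                           replicates: int = 2000) -> PosteriorGrid:
    """Pseudo-posterior π*(ψ|y) ∝ exp{ℓp(ψ) + ∫m} on an adaptive grid.

    ``replicates`` controls the parametric-bootstrap profile-cumulant
    estimates when the model has nuisance parameters and the adjustment has
    no closed form.
    """
    cfg = grid_config or GridConfig()
    idx = model.interest_index if interest_index is None else interest_index
    center, se = _center_and_se(model, data, idx, prior_kind)

    lo, hi = model.support[idx]
    span = cfg.span_se
    for expansion in range(cfg.max_expansions + 1):
        a, b = center - span * se, center + span * se
        if np.isfinite(lo):
            a = max(a, lo + (center - lo) * 1e-6)
        if np.isfinite(hi):
            b = min(b, hi - (hi - center) * 1e-6)

        if prior_kind == "firth" and isinstance(model, LogisticRegression):
            logpost = lambda p: _penalized_profile_logpost(model, p, data, idx)
        else:
            spline = _correction_spline(model, data, idx, prior_kind, (a, b),
                                        cfg, replicates, seed)
            prior_integral = spline.antiderivative()
            if model.dim == 1:
                def logpost(p: float, _pi=prior_integral) -> float:
                    return model.loglik([p], data) + float(_pi(p))
            else:
                warm = {"lam": None}

                def logpost(p: float, _pi=prior_integral) -> float:
                    lam = corrections._maximize_nuisance(
                        model, p, data, idx, start=warm["lam"])
                    warm["lam"] = lam
                    return model.loglik(corrections._assemble(p, lam, idx),
                                        data) + float(_pi(p))

        psi = np.linspace(a, b, cfg.points)
        logdens = np.array([logpost(p) for p in psi])

        def refine(left: float, right: float) -> float:
            res = optimize.minimize_scalar(lambda p: -logpost(p),
                                           bounds=(left, right), method="bounded",
                                           options={"xatol": 1e-10})
            return res.x

        grid = PosteriorGrid.from_log_density(
            psi, logdens, mode_refiner=refine,
            meta={"prior_kind": prior_kind, "center": center, "se": se,
                  "seed": seed, "interest_index": idx, "expansions": expansion})
        if grid.boundary_mass() < cfg.boundary_tol:
            return grid
        span *= 2.0
    if prior_kind in ("none", "flat"):
        direction = 1 if grid.density[-1] > grid.density[0] else -1
        raise ImproperPosteriorError(
            "flat pseudo-posterior does not decay within the expanded grid "
            f"(drift towards {'+' if direction > 0 else '-'}infinity)", direction)
    return grid


def quadratic_pseudo_posterior(model: ParametricModel, data: Dataset,
                               interest_index: Optional[int] = None,
                               correction_kind: str = "median",
                               grid_config: Optional[GridConfig] = None,
                               seed: Optional[int] = None,
                               replicates: int = 2000,
                               curvature_at: str = "psi") -> PosteriorGrid:
    """First-order (Rao-score) form: density ∝ exp{−tp(ψ)² / (2 jp(ψ))}.

    jp is evaluated at ψ by default (score-statistic convention);
    ``curvature_at="psi-hat"`` freezes it at the estimate instead.
    """
    return _quadratic_impl(model, data, interest_index, correction_kind,
                           grid_config, seed, replicates,
                           curvature_at=curvature_at)


def _quadratic_impl(model, data, interest_index, correction_kind, grid_config,
                    seed, replicates, curvature_at="psi"):
    cfg = grid_config or GridConfig()
    idx = model.interest_index if interest_index is None else interest_index
    center, se = _center_and_se(model, data, idx, correction_kind)
    jp_hat = 1.0 / se ** 2

    a, b = center - cfg.span_se * se, center + cfg.span_se * se
    lo, hi = model.support[idx]
    if np.isfinite(lo):
        a = max(a, lo + (center - lo) * 1e-6)
    if np.isfinite(hi):
        b = min(b, hi - (hi - center) * 1e-6)
    spline = _correction_spline(model, data, idx, correction_kind, (a, b),
                                cfg, replicates, seed)

    def tp(p: float) -> float:
        return corrections.profile_score(model, p, data, interest_index=idx) \
            + float(spline(p))
    psi = np.linspace(a, b, cfg.points)
    logdens = np.empty_like(psi)
    trimmed = False
    for i, p in enumerate(psi):
        t = tp(p)
        if curvature_at == "psi":
            jp = corrections.profile_observed_info(model, p, data,
                                                   interest_index=idx)
        else:
            jp = jp_hat
        if jp <= 0:
            logdens[i] = -np.inf
            trimmed = True
        else:
            logdens[i] = -0.5 * t * t / jp
    keep = np.isfinite(logdens)
    grid = PosteriorGrid.from_log_density(
        psi[keep], logdens[keep],
        meta={"prior_kind": correction_kind, "center": center, "se": se,
              "curvature_at": curvature_at, "trimmed": trimmed,
              "interest_index": idx})
    return grid


# --------------------------------------------------------------------------
# HPD intervals
# --------------------------------------------------------------------------

def _local_maxima(dens: np.ndarray, rel_prominence: float = 0.01) -> int:
    peaks = 0
    thresh = rel_prominence * float(np.max(dens))
    for i in range(1, len(dens) - 1):
        if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1] and dens[i] > thresh:
            peaks += 1
    return max(peaks, 1)


def hpd_interval(grid: PosteriorGrid, level: float = 0.95,
                 tol: float = 1e-4,
                 weight: Optional[np.ndarray] = None) -> HpdResult:
    """Highest-density superlevel set with mass = level (bisection on height).

    ``weight`` (per grid point) switches the mass to an information-weighted
    measure, making the set's probability content invariant under monotone
    reparameterization of the interest parameter.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    dens = grid.density
    md = None
    if weight is not None:
        md = dens * np.asarray(weight, dtype=float)
        md = md / np.trapezoid(md, grid.psi)
    lo_h, hi_h = 0.0, float(np.max(dens))
    for _ in range(200):
        c = 0.5 * (lo_h + hi_h)
        mass, intervals = superlevel_mass(grid.psi, dens, c, mass_density=md)
        if abs(mass - level) < tol * 0.5:
            break
        if mass > level:
            lo_h = c
        else:
            hi_h = c
    mass, intervals = superlevel_mass(grid.psi, dens, c, mass_density=md)
    if not intervals:
        intervals = [(float(grid.psi[0]), float(grid.psi[-1]))]
    multimodal = _local_maxima(dens) > 1 and len(intervals) > 1
    return HpdResult(intervals=intervals, level=level, threshold=float(c),
                     multimodal=multimodal)


# --------------------------------------------------------------------------
# rejection ABC
# --------------------------------------------------------------------------

def _decile_summary(samples: np.ndarray) -> np.ndarray:
    """Order statistics at deciles (0.1 … 0.9), rows = samples."""
    qs = np.linspace(0.1, 0.9, 9)
    return np.quantile(samples, qs, axis=-1).T if samples.ndim == 2 \
        else np.quantile(samples, qs)


def abc_posterior(model: ParametricModel, prior_sampler, data: Dataset,
                  n_draws: int = 100000, accept_fraction: float = 0.05,
                  summary: str = "sorted-sample",
                  seed: Optional[int] = None) -> AbcSample:
    """Rejection ABC: keep the prior draws whose simulated data are closest.

    The default summary is the vector of sample deciles, standardized by the
    observed-data scale; the distance is Euclidean.  Acceptance keeps exactly
    ``round(accept_fraction * n_draws)`` draws (the empirical-quantile rule).
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = np.asarray(prior_sampler(rng, n_draws), dtype=float)
    y_obs = data.y
    scale = float(np.std(y_obs))
    if scale == 0.0:
        raise ValueError("degenerate observed data: zero variance summary")

    if summary == "sorted-sample":
        s_obs = _decile_summary(y_obs)
        summarize = _decile_summary
    elif summary == "estimate":
        s_obs = np.atleast_1d(model.initial_guess(data))

        def summarize(mat):
            return np.array([model.initial_guess(Dataset.from_values(row))
                             for row in mat])
    elif summary == "score-at-grid":
        guess = float(model.initial_guess(data)[0])
        tgrid = np.linspace(guess - 2.0, guess + 2.0, 5)
        lo, hi = model.support[0]
        tgrid = np.clip(tgrid, lo + 1e-3 if np.isfinite(lo) else -np.inf,
                        hi - 1e-3 if np.isfinite(hi) else np.inf)

        def summarize(mat):
            mat = np.atleast_2d(mat)
            return np.column_stack([model.score_rowwise(t, mat).mean(axis=1)
                                    for t in tgrid])
        s_obs = summarize(y_obs[None, :])[0]
    else:
        raise ValueError(f"unknown summary {summary!r}")

    distances = np.empty(n_draws)
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        sims = model.simulate_matrix(draws[start:stop], n, rng)
        s_sim = summarize(sims)
        distances[start:stop] = np.linalg.norm(
            (np.atleast_2d(s_sim) - s_obs) / scale, axis=-1)

    k = int(round(accept_fraction * n_draws))
    k = max(min(k, n_draws), 1)
    threshold = float(np.partition(distances, k - 1)[k - 1])
    accepted = np.zeros(n_draws, dtype=bool)
    accepted[np.argpartition(distances, k - 1)[:k]] = True
    return AbcSample(draws=draws, distances=distances,
                     acceptance_threshold=threshold, accepted=accepted,
                     n_draws=n_draws, acceptance_fraction=accept_fraction,
                     seed=seed)


def map_from_samples(samples: np.ndarray, bandwidth_rule: str = "silverman",
                     grid_points: int = 512) -> tuple[float, bool]:
    """Posterior mode from samples via a Gaussian KDE, with multimodality flag."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValueError(f"need at least 100 samples, got {samples.size}")
    if np.ptp(samples) == 0.0:
        return float(samples[0]), False
    kde = stats.gaussian_kde(samples, bw_method=bandwidth_rule)
    lo, hi = float(np.min(samples)), float(np.max(samples))
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    k = int(np.argmax(dens))
    left = grid[max(k - 1, 0)]
    right = grid[min(k + 1, grid_points - 1)]
    res = optimize.minimize_scalar(lambda x: -float(kde(x)[0]),
                                   bounds=(left, right), method="bounded",
                                   options={"xatol": 1e-8})
    multimodal = _local_maxima(dens) > 1
    return float(res.x), multimodal


def grid_prior_sampler(log_prior: Callable[[np.ndarray], np.ndarray],
                       bounds: tuple[float, float],
                       grid_points: int = 2001):
    """Sampler for a prior known through its log density, by inverse CDF.

    Improper priors (e.g. flat, Jeffreys on an unbounded range) are
    truncated to ``bounds``.
    """
    a, b = bounds
    grid = np.linspace(a, b, grid_points)
    logp = np.asarray(log_prior(grid), dtype=float)
    dens = np.exp(logp - np.max(logp))
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    # make strictly increasing for interpolation
    cdf, uniq = np.unique(cdf, return_index=True)
    grid_u = grid[uniq]

    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.random(size)
        return np.interp(u, cdf, grid_u)

    return sampler
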