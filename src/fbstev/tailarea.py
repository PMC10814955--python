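"""Higher-order tail-area machinery for marginal posteriors.

Implements the Laplace approximation to the marginal posterior of a scalar
interest parameter,

    πm(ψ|y) ∝ exp{ℓp(ψ) − ℓp(ψ̂)} · |jλλ(ψ, λ̂ψ)|^{-1/2} · π(ψ, λ̂ψ),

the profile likelihood root rp(ψ) = sign(ψ̂−ψ)[2{ℓp(ψ̂)−ℓp(ψ)}]^{1/2}, the
Bayesian correction factor

    qB(ψ) = ℓp′(ψ) jp(ψ̂)^{-1/2}
            {|jλλ(ψ, λ̂ψ)| / |jλλ(ψ̂, λ̂)|}^{1/2}
            {π(ψ̂, λ̂)/π(ψ, λ̂ψ)} {r(ψ, λ̂ψ)/r(ψ̂, λ̂)},

the modified root rB*(ψ) = rp + log(qB/rp)/rp, and the O(n^{-3/2}) tail-area
approximation ∫_{ψ0}^∞ πms(ψ|y) dψ ≈ Φ(rB*(ψ0)).  A third-order e-value is
obtained by locating the point ψ0* with marginal-surprise density equal to
that at ψ0 on the other side of the mode.

rB* is 0/0 at ψ = ψ̂; inside a configurable window |rp| < 0.05 it is replaced
by a cubic interpolation through values just outside the window (the
standard practical treatment in higher-order likelihood asymptotics).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

from . import corrections
from .evalue import EvalueResult, Hypothesis
from .models import Dataset, ParametricModel
from .pseudo_posterior import PosteriorGrid

__all__ = [
    "TailAreaContext",
    "RStarValue",
    "make_context",
    "laplace_marginal_posterior",
    "profile_likelihood_root",
    "qB_factor",
    "rstar_bayes",
    "tail_area_probability",
    "evalue_tailarea",
    "flat_prior",
    "jeffreys_prior",
    "invwishart_sigma_prior",
]

SINGULAR_RP = 0.05


def flat_prior(psi: float, lam: np.ndarray) -> float:
    return 1.0


def invwishart_sigma_prior(df: float = 1.0):
    """Inverse-Wishart(df, I) on the error covariance, flat on β.

    For the bivariate regression parameterization (β0, β1, β2, σ², ρ) with
    Σ = σ² [[1, ρ], [ρ, 1]]: density ∝ |Σ|^{-(df+3)/2} exp{−tr(Σ⁻¹)/2}
    evaluated at Σ(σ², ρ), up to the (immaterial) constant.  Interest is ρ,
    so λ = (β0, β1, β2, σ²).
    """
    def prior(psi: float, lam: np.ndarray) -> float:
        rho = float(psi)
        s2 = float(np.atleast_1d(lam)[-1])
        if not (-1.0 < rho < 1.0 and s2 > 0):
            return 0.0
        logdet = 2.0 * math.log(s2) + math.log1p(-rho * rho)
        trace_inv = 2.0 / (s2 * (1.0 - rho * rho))
        return math.exp(-0.5 * (df + 3.0) * logdet - 0.5 * trace_inv)
    return prior


def jeffreys_prior(model: ParametricModel, data: Dataset):
    """Jeffreys prior |i(θ)|^{1/2} as a (ψ, λ) callable for this model."""
    def prior(psi: float, lam: np.ndarray) -> float:
        theta = corrections._assemble(psi, np.atleast_1d(lam),
                                      model.interest_index) \
            if model.dim > 1 else np.array([psi])
        info = model.expected_info(theta, data=data, n=len(data))
        sign, logdet = np.linalg.slogdet(np.atleast_2d(info))
        if sign <= 0:
            raise ValueError("information not positive definite")
        return math.exp(0.5 * logdet)
    return prior


@dataclasses.dataclass
class TailAreaContext:
    model: ParametricModel
    data: Dataset
    interest_index: int
    psi_hat: float
    lam_hat: np.ndarray
    lp_hat: float
    jp_hat: float
    log_jll_hat: float
    prior: Callable[[float, np.ndarray], float]
    reference: Callable[[float, np.ndarray], float]
    _lam_cache: dict = dataclasses.field(default_factory=dict)

    def constrained(self, psi: float) -> np.ndarray:
        key = round(float(psi), 12)
        if key not in self._lam_cache:
            if self.model.dim == 1:
                self._lam_cache[key] = np.empty(0)
            else:
                start = None
                if self._lam_cache:
                    nearest = min(self._lam_cache,
                                  key=lambda k: abs(k - key))
                    start = self._lam_cache[nearest]
                self._lam_cache[key] = corrections._maximize_nuisance(
                    self.model, psi, self.data, self.interest_index,
                    start=start)
        return self._lam_cache[key]

    def profile_loglik(self, psi: float) -> float:
        lam = self.constrained(psi)
        if self.model.dim == 1:
            return self.model.loglik([psi], self.data)
        theta = corrections._assemble(psi, lam, self.interest_index)
        return self.model.loglik(theta, self.data)

    def profile_score(self, psi: float) -> float:
        return corrections.profile_score(self.model, psi, self.data,
                                         interest_index=self.interest_index,
                                         lam=self.constrained(psi))

    def log_jll(self, psi: float) -> float:
        """log |jλλ(ψ, λ̂ψ)| (zero when there are no nuisance parameters)."""
        if self.model.dim == 1:
            return 0.0
        lam = self.constrained(psi)
        theta = corrections._assemble(psi, lam, self.interest_index)
        j = self.model.observed_info(theta, self.data)
        nuis = [i for i in range(self.model.dim) if i != self.interest_index]
        sign, logdet = np.linalg.slogdet(j[np.ix_(nuis, nuis)])
        if sign <= 0:
            raise ValueError(f"nuisance information block singular at psi={psi}")
        return float(logdet)


@dataclasses.dataclass
class RStarValue:
    rp: float
    qB: float
    rstar: float
    interpolated: bool = False


def make_context(model: ParametricModel, data: Dataset,
                 interest_index: Optional[int] = None,
                 prior: Optional[Callable] = None,
                 reference: Optional[Callable] = None) -> TailAreaContext:
    """Assemble the profile-likelihood/prior ingredients for qB and rB*."""
    idx = model.interest_index if interest_index is None else interest_index
    theta_hat = corrections.full_mle(model, data)
    psi_hat = float(theta_hat[idx])
    nuis = [i for i in range(model.dim) if i != idx]
    lam_hat = theta_hat[nuis]
    lp_hat = float(model.loglik(theta_hat, data))
    jp_hat = corrections.profile_observed_info(model, psi_hat, data,
                                               interest_index=idx)
    if jp_hat <= 0:
        raise ValueError("profile information not positive at the MLE")
    ctx = TailAreaContext(model=model, data=data, interest_index=idx,
                          psi_hat=psi_hat, lam_hat=lam_hat, lp_hat=lp_hat,
                          jp_hat=jp_hat, log_jll_hat=0.0,
                          prior=prior or flat_prior,
                          reference=reference or flat_prior)
    ctx._lam_cache[round(psi_hat, 12)] = lam_hat
    ctx.log_jll_hat = ctx.log_jll(psi_hat)
    return ctx


def laplace_marginal_posterior(ctx: TailAreaContext,
                               psi_grid: np.ndarray) -> PosteriorGrid:
    """Laplace marginal posterior density on a grid, renormalized."""
    psi_grid = np.asarray(psi_grid, dtype=float)
    logdens = np.empty_like(psi_grid)
    for i, p in enumerate(psi_grid):
        lam = ctx.constrained(p)
        logdens[i] = (ctx.profile_loglik(p) - ctx.lp_hat
                      - 0.5 * (ctx.log_jll(p) - ctx.log_jll_hat)
                      + math.log(ctx.prior(p, lam)))
    return PosteriorGrid.from_log_density(psi_grid, logdens,
                                          meta={"kind": "laplace-marginal"})


def profile_likelihood_root(ctx: TailAreaContext, psi: float) -> float:
    """rp(ψ) = sign(ψ̂ − ψ) [2{ℓp(ψ̂) − ℓp(ψ)}]^{1/2}."""
    drop = ctx.lp_hat - ctx.profile_loglik(psi)
    if drop < -1e-8 * max(1.0, abs(ctx.lp_hat)):
        raise RuntimeError(
            f"profile log-likelihood exceeds its maximum at psi={psi}: "
            f"inner optimization inconsistent (drop={drop})")
    return math.copysign(math.sqrt(max(2.0 * drop, 0.0)), ctx.psi_hat - psi)


def qB_factor(ctx: TailAreaContext, psi: float) -> float:
    """Bayesian correction factor entering the modified root."""
    lam = ctx.constrained(psi)
    prior_ratio = ctx.prior(ctx.psi_hat, ctx.lam_hat) / ctx.prior(psi, lam)
    ref_ratio = ctx.reference(psi, lam) / ctx.reference(ctx.psi_hat, ctx.lam_hat)
    if prior_ratio <= 0 or ref_ratio <= 0:
        raise ValueError("prior and reference must be strictly positive")
    jll_ratio = math.exp(0.5 * (ctx.log_jll(psi) - ctx.log_jll_hat))
    return (ctx.profile_score(psi) / math.sqrt(ctx.jp_hat)
            * jll_ratio * prior_ratio * ref_ratio)


def _rstar_raw(ctx: TailAreaContext, psi: float) -> RStarValue:
    rp = profile_likelihood_root(ctx, psi)
    qb = qB_factor(ctx, psi)
    ratio = qb / rp
    if ratio <= 0:
        raise ValueError(f"qB/rp = {ratio} not positive at psi={psi} "
                         f"(rp={rp}, qB={qb})")
    return RStarValue(rp=rp, qB=qb, rstar=rp + math.log(ratio) / rp)


def _psi_at_rp(ctx: TailAreaContext, target_rp: float) -> float:
    """ψ with rp(ψ) = target_rp (target > 0 means left of ψ̂)."""
    se = 1.0 / math.sqrt(ctx.jp_hat)
    side = -1.0 if target_rp > 0 else 1.0
    lo, hi = ctx.model.support[ctx.interest_index]
    f = lambda p: profile_likelihood_root(ctx, p) - target_rp
    step = se * abs(target_rp)
    a = ctx.psi_hat
    for _ in range(60):
        b = a + side * step
        if np.isfinite(lo):
            b = max(b, lo + (ctx.psi_hat - lo) * 1e-9)
        if np.isfinite(hi):
            b = min(b, hi - (hi - ctx.psi_hat) * 1e-9)
        if f(ctx.psi_hat) * f(b) < 0 or f(b) == 0.0:
            return optimize.brentq(f, min(ctx.psi_hat, b), max(ctx.psi_hat, b),
                                   xtol=1e-12)
        step *= 2.0
    raise RuntimeError(f"could not bracket rp level {target_rp}")


def rstar_bayes(ctx: TailAreaContext, psi: float,
                window: float = SINGULAR_RP) -> RStarValue:
    """Modified likelihood root rB*(ψ), interpolated across the singularity.

    For |rp(ψ)| < ``window`` the 0/0 form is replaced by a cubic through
    rB* evaluated at the ψ values where |rp| equals ``window`` and
    2·``window`` on both sides, and the result is flagged.
    """
    rp = profile_likelihood_root(ctx, psi)
    if abs(rp) >= window:
        return _rstar_raw(ctx, psi)
    nodes = []
    for level in (2.0 * window, window, -window, -2.0 * window):
        p = _psi_at_rp(ctx, level)
        nodes.append((p, _rstar_raw(ctx, p).rstar))
    xs = np.array([p for p, _ in nodes])
    ys = np.array([v for _, v in nodes])
    coef = np.polyfit(xs - ctx.psi_hat, ys, 3)
    val = float(np.polyval(coef, psi - ctx.psi_hat))
    qb = qB_factor(ctx, psi)
    return RStarValue(rp=rp, qB=qb, rstar=val, interpolated=True)


def tail_area_probability(ctx: TailAreaContext, psi0: float) -> float:
    """Φ(rB*(ψ0)) ≈ upper tail mass of the marginal surprise posterior."""
    return float(stats.norm.cdf(rstar_bayes(ctx, psi0).rstar))


def _default_grid(ctx: TailAreaContext, span: float = 8.0,
                  points: int = 801) -> np.ndarray:
    se = 1.0 / math.sqrt(ctx.jp_hat)
    lo, hi = ctx.model.support[ctx.interest_index]
    a = ctx.psi_hat - span * se
    b = ctx.psi_hat + span * se
    # keep clear of finite support boundaries by more than any
    # finite-difference step taken by the information evaluators
    if np.isfinite(lo):
        a = max(a, lo + max((ctx.psi_hat - lo) * 1e-6,
                            1e-4 * max(1.0, abs(lo))))
    if np.isfinite(hi):
        b = min(b, hi - max((hi - ctx.psi_hat) * 1e-6,
                            1e-4 * max(1.0, abs(hi))))
    return np.linspace(a, b, points)


def evalue_tailarea(ctx: TailAreaContext, hyp: Hypothesis,
                    grid: Optional[np.ndarray] = None) -> EvalueResult:
    """Third-order e-value 1 − Φ(rB*(ψhi)) + Φ(rB*(ψlo)).

    (ψlo, ψhi) is the ordered pair {ψ0, ψ0*}, with ψ0* the point on the
    opposite side of the marginal-surprise mode with equal density.
    Restricted to unimodal marginal surprise densities.
    """
    psi0 = float(hyp.null_value)
    psis = _default_grid(ctx) if grid is None else np.asarray(grid, float)
    if psi0 < psis[0] or psi0 > psis[-1]:
        se = 1.0 / math.sqrt(ctx.jp_hat)
        span = abs(psi0 - ctx.psi_hat) / se + 4.0
        psis = _default_grid(ctx, span=span)
    marg = laplace_marginal_posterior(ctx, psis)
    ref = np.array([ctx.reference(p, ctx.constrained(p)) for p in psis])
    surprise = marg.density / ref
    from .pseudo_posterior import _local_maxima
    multimodal = _local_maxima(surprise) > 1

    log_s = np.log(np.maximum(surprise, 1e-300))
    k_mode = int(np.argmax(surprise))
    mode = float(psis[k_mode])
    s0 = float(np.interp(psi0, psis, log_s))

    if abs(psi0 - mode) < 1e-10 * max(1.0, abs(mode)):
        return EvalueResult(ev=1.0, method="tail-area",
                            diagnostics={"mode": mode, "multimodal": multimodal})

    f = lambda p: float(np.interp(p, psis, log_s)) - s0
    if psi0 < mode:
        a, b = mode, psis[-1]
    else:
        a, b = psis[0], mode
    if f(b) > 0:  # equal-density point beyond the grid: extend
        se = 1.0 / math.sqrt(ctx.jp_hat)
        psis = _default_grid(ctx, span=2.0 * (abs(psi0 - ctx.psi_hat) / se + 8.0))
        marg = laplace_marginal_posterior(ctx, psis)
        ref = np.array([ctx.reference(p, ctx.constrained(p)) for p in psis])
        surprise = marg.density / ref
        log_s = np.log(np.maximum(surprise, 1e-300))
        s0 = float(np.interp(psi0, psis, log_s))
        f = lambda p: float(np.interp(p, psis, log_s)) - s0
        k_mode = int(np.argmax(surprise))
        mode = float(psis[k_mode])
        if psi0 < mode:
            a, b = mode, psis[-1]
        else:
            a, b = psis[0], mode
        if f(b) * f(a) > 0:
            raise RuntimeError("could not bracket the equal-density point psi0*")
    psi0_star = optimize.brentq(f, a, b, xtol=1e-10)

    lo_p, hi_p = sorted((psi0, float(psi0_star)))
    # Φ(rB*) approximates the upper tail from its argument; the mass of the
    # HPD-style interval (ψlo, ψhi) is Φ(rB*(ψlo)) − Φ(rB*(ψhi))
    ev = 1.0 - (tail_area_probability(ctx, lo_p)
                - tail_area_probability(ctx, hi_p))
    return EvalueResult(ev=ev, method="tail-area",
                        tangential_boundaries=(lo_p, hi_p),
                        surprise_level=float(math.exp(s0)),
                        diagnostics={"mode": mode, "psi0_star": float(psi0_star),
                                     "multimodal": multimodal})
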