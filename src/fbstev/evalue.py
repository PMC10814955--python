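"""FBST e-values for a scalar interest parameter.

The e-value for the sharp hypothesis H0: ψ = ψ0 is the posterior mass *not*
in the tangential set T = {ψ : πs(ψ|y) > s*}, where πs is the posterior
surprise function (density over a reference function, flat by default on the
pseudo-posterior path) and s* its supremum over the null set:

    ev = 1 − ∫_T πs(ψ|y) dψ.

Small ev is evidence against H0.  Besides the exact grid computation, two
first-order normal approximations are provided (Wald-type, centred at the
MLE or at the median-bias-reduced estimate, and score-type, built from the
modified (profile) score), together with the asymptotic null distribution
V(c) = Q(d−h, Q⁻¹(d, c)) of the e-value (Q the chi-square CDF).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional

import numpy as np
from scipy import stats

from . import corrections, pseudo_posterior as pp
from .models import Dataset, ParametricModel

__all__ = [
    "Hypothesis",
    "EvalueResult",
    "evalue_exact_1d",
    "evalue_wald",
    "evalue_score",
    "evalue_null_cdf",
    "evalue_for_hypothesis",
]


@dataclasses.dataclass
class Hypothesis:
    null_value: float
    interest_index: int = 0


@dataclasses.dataclass
class EvalueResult:
    ev: float
    method: str  # exact-grid | wald-mle | wald-median | score-scalar | score-profile | tail-area
    tangential_boundaries: tuple[float, ...] = ()
    surprise_level: float = float("nan")
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        # clamp the tiny numerical overshoots of grid integration
        self.ev = float(min(max(self.ev, 0.0), 1.0))


def evalue_exact_1d(grid: pp.PosteriorGrid, hyp: Hypothesis,
                    reference: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                    weight: Optional[np.ndarray] = None) -> EvalueResult:
    """Exact (grid) e-value: 1 − normalized-surprise mass of {surprise > s*}.

    ``weight`` (per grid point, e.g. √jp(ψ)) computes the tangential-set
    mass under the information-weighted measure: the superlevel set is still
    cut on the surprise function, so the e-value becomes exactly invariant
    under monotone reparameterization of the interest parameter (for a flat
    weight the plain density mass is returned).
    """
    psi0 = float(hyp.null_value)
    if not grid.psi[0] <= psi0 <= grid.psi[-1]:
        raise ValueError(f"null value {psi0} outside the posterior grid "
                         f"[{grid.psi[0]:.4g}, {grid.psi[-1]:.4g}]; rebuild the "
                         "grid with a wider span")
    if reference is None:
        surprise = grid.density.copy()
    else:
        ref = np.asarray(reference(grid.psi), dtype=float)
        if np.any(ref <= 0) or not np.all(np.isfinite(ref)):
            raise ValueError("reference function must be finite and positive")
        surprise = grid.density / ref
        norm = float(np.trapezoid(surprise, grid.psi))
        if not np.isfinite(norm) or norm <= 0:
            raise ValueError("surprise function does not normalize")
        surprise = surprise / norm
    mass_density = None
    if weight is not None:
        mass_density = surprise * np.asarray(weight, dtype=float)
        mass_density /= np.trapezoid(mass_density, grid.psi)
    s_star = float(np.interp(psi0, grid.psi, surprise))
    mass, intervals = pp.superlevel_mass(grid.psi, surprise, s_star,
                                         mass_density=mass_density)
    boundaries = tuple(float(b) for pair in intervals for b in pair
                       if grid.psi[0] < b < grid.psi[-1])
    return EvalueResult(ev=1.0 - mass, method="exact-grid",
                        tangential_boundaries=boundaries,
                        surprise_level=s_star,
                        diagnostics={"n_grid": len(grid.psi),
                                     "n_components": len(intervals),
                                     "mode": grid.mode})


def evalue_wald(estimate: float, curvature: float, hyp: Hypothesis,
                estimator: str = "mle") -> EvalueResult:
    """First-order Wald-type e-value 2{1 − Φ(|ψ0 − est| √curvature)}.

    ``curvature`` is the (profile) information at the estimate; ``estimator``
    tags whether the centring point is the MLE or the median-bias-reduced
    estimate (the two approximations differ only in location).
    """
    if curvature <= 0:
        raise ValueError("curvature must be positive")
    z = abs(hyp.null_value - estimate) * math.sqrt(curvature)
    return EvalueResult(ev=2.0 * stats.norm.sf(z),
                        method=f"wald-{estimator}",
                        diagnostics={"z": z, "estimate": estimate})


def evalue_score(t_value: float, information: float, hyp: Hypothesis,
                 profile: bool = False) -> EvalueResult:
    """Score-type e-value 2{1 − Φ(|t(ψ0)| / √i(ψ0))}.

    Built from the modified (profile) score at the null point; invariant
    under monotone reparameterization because t/√i is.
    """
    if information <= 0:
        raise ValueError("information must be positive")
    z = abs(t_value) / math.sqrt(information)
    return EvalueResult(ev=2.0 * stats.norm.sf(z),
                        method="score-profile" if profile else "score-scalar",
                        diagnostics={"z": z, "t": t_value})


def evalue_null_cdf(c: float, d: int = 1, h: int = 0) -> float:
    """Asymptotic null CDF of the e-value: V(c) = Q(d−h, Q⁻¹(d, c)).

    d = dim(Θ), h = dim(Θ0); for d = 1, h = 0 this is the identity, i.e.
    e-values are asymptotically Uniform(0, 1) under H0.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must lie in [0, 1]")
    if not 0 <= h < d:
        raise ValueError("need 0 <= h < d")
    if c in (0.0, 1.0):
        return float(c)
    x = stats.chi2.ppf(c, d)
    return float(stats.chi2.cdf(x, d - h))


def information_weight(model: ParametricModel, data: Dataset, idx: int,
                       psi_grid: np.ndarray, subgrid: int = 41) -> np.ndarray:
    """√(profile/expected information) per grid point, splined from a coarse grid.

    This is the density of the parameterization-invariant information
    measure √i(ψ)dψ; using it for tangential-set masses makes exact-grid
    e-values and HPD contents invariant under monotone interest
    reparameterizations.
    """
    from scipy.interpolate import PchipInterpolator

    psi_grid = np.asarray(psi_grid, dtype=float)
    sub = np.linspace(psi_grid[0], psi_grid[-1], min(subgrid, len(psi_grid)))
    vals = np.empty_like(sub)
    for i, p in enumerate(sub):
        if model.dim == 1:
            info = float(model.expected_info([p], data=data, n=len(data))[0, 0])
        else:
            info = corrections.profile_observed_info(model, p, data,
                                                     interest_index=idx)
        vals[i] = math.sqrt(max(info, 1e-300))
    return np.asarray(PchipInterpolator(sub, vals)(psi_grid))


def evalue_for_hypothesis(model: ParametricModel, data: Dataset,
                          hyp: Hypothesis, method: str = "exact-grid",
                          prior_kind: str = "median",
                          seed: Optional[int] = None,
                          replicates: int = 2000,
                          grid_config: Optional[pp.GridConfig] = None
                          ) -> EvalueResult:
    """Dispatch to the requested e-value backend.

    method ∈ {"exact-grid", "wald", "wald-mle", "score", "tail-area"}.
    """
    idx = hyp.interest_index if hyp.interest_index is not None \
        else model.interest_index
    if method == "exact-grid":
        grid = pp.build_pseudo_posterior(model, data, interest_index=idx,
                                         prior_kind=prior_kind,
                                         grid_config=grid_config, seed=seed,
                                         replicates=replicates)
        if not grid.psi[0] <= hyp.null_value <= grid.psi[-1]:
            cfg = grid_config or pp.GridConfig()
            extra = abs(hyp.null_value - grid.meta["center"]) / grid.meta["se"] + 4.0
            cfg = dataclasses.replace(cfg, span_se=max(cfg.span_se, extra))
            grid = pp.build_pseudo_posterior(model, data, interest_index=idx,
                                             prior_kind=prior_kind,
                                             grid_config=cfg, seed=seed,
                                             replicates=replicates)
        w = information_weight(model, data, idx, grid.psi)
        res = evalue_exact_1d(grid, hyp, weight=w)
        res.diagnostics["prior_kind"] = prior_kind
        res.diagnostics["mass_measure"] = "information"
        return res
    if method in ("wald", "wald-median", "wald-mle"):
        if method == "wald-mle":
            est = float(corrections.full_mle(model, data)[idx])
            tag = "mle"
        else:
            if model.dim == 1:
                fit = corrections.solve_modified_score(model, data, "median")
            else:
                fit = corrections.solve_modified_profile_score(
                    model, data, interest_index=idx, replicates=replicates,
                    seed=seed)
            est, tag = fit.value, "median"
        jp = corrections.profile_observed_info(model, est, data,
                                               interest_index=idx)
        return evalue_wald(est, jp, hyp, estimator=tag)
    if method == "score":
        psi0 = float(hyp.null_value)
        if model.dim == 1:
            corr = corrections.make_correction(model, prior_kind if prior_kind
                                               != "flat" else "none", data=data)
            t0 = float(model.score([psi0], data)[0]) + corr(psi0)
            info = float(model.expected_info([psi0], data=data,
                                             n=len(data))[0, 0])
            return evalue_score(t0, info, hyp, profile=False)
        lam = corrections._maximize_nuisance(model, psi0, data, idx)
        cum = corrections.profile_cumulants(model, psi0, data, lam_hat_psi=lam,
                                            interest_index=idx,
                                            replicates=replicates, seed=seed)
        t0 = corrections.profile_score(model, psi0, data, interest_index=idx,
                                       lam=lam) \
            + corrections.median_correction_profile(cum)
        jp0 = corrections.profile_observed_info(model, psi0, data,
                                                interest_index=idx, lam=lam)
        return evalue_score(t0, jp0, hyp, profile=True)
    if method == "tail-area":
        from . import tailarea
        ctx = tailarea.make_context(model, data, interest_index=idx)
        return tailarea.evalue_tailarea(ctx, hyp)
    raise ValueError(f"unknown e-value method {method!r}")
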