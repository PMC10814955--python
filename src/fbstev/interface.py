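"""Configuration, dataset/result I/O and experiment harnesses.

Harnesses reproduce the study designs used to characterize the method: the
null-calibration experiment (distribution of first-order e-values under a
true sharp hypothesis), the skew-normal ABC pipeline comparing priors across
sample sizes, and the fixture generators (including a synthetic
quasi-separated logistic dataset mimicking the endometrial cancer grade
study: n = 79, one binary risk factor aligned with the response on one
stratum, two continuous covariates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import interpolate, optimize, stats

from . import corrections, evalue as ev_mod, pseudo_posterior as pp
from .corrections import DivergenceError
from .models import (BivariateRegression, Dataset, ExponentialScale,
                     LogisticRegression, NormalMeanVariance, NormalVariance,
                     ParametricModel, SkewNormalShape, exponential_rate_model,
                     detect_monotone_likelihood, poisson_logmean_model)
from .pseudo_posterior import GridConfig, ImproperPosteriorError

__all__ = [
    "RunConfig",
    "ResultRecord",
    "NullCalibrationResult",
    "model_from_name",
    "run_single_analysis",
    "run_null_calibration",
    "run_table1_experiment",
    "generate_fixture",
    "load_endometrial",
    "skewnormal_logprior",
]

__version__ = "0.1.0"

_FAMILIES = {
    "exponential-rate": lambda cfg: exponential_rate_model(),
    "poisson-logmean": lambda cfg: poisson_logmean_model(),
    "exponential-scale": lambda cfg: ExponentialScale(),
    "normal-variance": lambda cfg: NormalVariance(),
    "normal-mean-variance": lambda cfg: NormalMeanVariance(),
    "skew-normal": lambda cfg: SkewNormalShape(),
    "logistic": lambda cfg: LogisticRegression(
        covariates=cfg.covariates, interest=cfg.interest, response=cfg.response),
    "bivariate-regression": lambda cfg: BivariateRegression(),
}

_STOCHASTIC_METHODS = {"abc"}


@dataclasses.dataclass
class RunConfig:
    model: str
    response: str = "y"
    covariates: tuple[str, ...] = ()
    interest: Optional[str] = None          # parameter name; default model choice
    null_values: tuple[float, ...] = ()
    prior_kind: str = "median"
    method: str = "exact-grid"              # exact-grid | wald | score | tail-area | abc
    cumulant_replicates: int = 2000
    grid_points: int = 801
    grid_span_se: float = 8.0
    profile_cache_points: int = 41
    hpd_level: float = 0.95
    seed: Optional[int] = None
    out: Optional[str] = None

    def __post_init__(self):
        if self.model not in _FAMILIES:
            raise ValueError(f"unknown model family {self.model!r}; "
                             f"choose from {sorted(_FAMILIES)}")
        if self.method in _STOCHASTIC_METHODS or self.prior_kind == "median":
            if self.seed is None:
                raise ValueError("a seed is mandatory for stochastic methods")
        self.null_values = tuple(float(v) for v in self.null_values)
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclasses.dataclass
class ResultRecord:
    config: dict
    config_hash: str
    version: str
    timestamp: float
    estimates: dict
    evalues: dict
    map_estimate: Optional[float]
    hpd: Optional[dict]
    warnings: list
    error: Optional[dict] = None

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ResultRecord":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def model_from_name(config: RunConfig) -> ParametricModel:
    return _FAMILIES[config.model](config)


def _interest_idx(model: ParametricModel, config: RunConfig) -> int:
    if config.interest is None:
        return model.interest_index
    return model.param_names.index(config.interest)


def run_single_analysis(config: RunConfig,
                        data: Dataset | str | Path) -> ResultRecord:
    """Execute one configured analysis and return a structured record."""
    if not isinstance(data, Dataset):
        data = Dataset.read_csv(data, response=config.response,
                                covariates=config.covariates or None)
    model = model_from_name(config)
    idx = _interest_idx(model, config)
    warnings: list[str] = []
    estimates: dict = {}
    evalues: dict = {}
    map_estimate = None
    hpd = None
    error = None

    flag, direction = detect_monotone_likelihood(model, data, interest_index=idx)
    if flag:
        warnings.append(
            f"monotone (profile) likelihood detected: unpenalized estimate "
            f"diverges towards {'+' if direction > 0 else '-'}infinity "
            "(quasi-complete separation in binary regression)")

    cfg = GridConfig(points=config.grid_points, span_se=config.grid_span_se,
                     profile_cache_points=config.profile_cache_points)
    try:
        if config.method in ("exact-grid", "abc"):
            grid = pp.build_pseudo_posterior(
                model, data, interest_index=idx, prior_kind=config.prior_kind,
                grid_config=cfg, seed=config.seed,
                replicates=config.cumulant_replicates)
            map_estimate = grid.mode
            w = ev_mod.information_weight(model, data, idx, grid.psi)
            hres = pp.hpd_interval(grid, config.hpd_level, weight=w)
            if hres.multimodal:
                warnings.append("posterior is multimodal; HPD is a union of intervals")
            hpd = {"level": hres.level, "intervals": hres.intervals}
            for psi0 in config.null_values:
                res = ev_mod.evalue_exact_1d(
                    grid, ev_mod.Hypothesis(psi0, interest_index=idx), weight=w)
                evalues[str(psi0)] = {"ev": res.ev, "method": res.method}
        else:
            for psi0 in config.null_values:
                res = ev_mod.evalue_for_hypothesis(
                    model, data, ev_mod.Hypothesis(psi0, interest_index=idx),
                    method=config.method, prior_kind=config.prior_kind,
                    seed=config.seed, replicates=config.cumulant_replicates)
                evalues[str(psi0)] = {"ev": res.ev, "method": res.method}
        if model.dim == 1:
            fit = corrections.solve_modified_score(model, data,
                                                   "median" if config.prior_kind
                                                   in ("median", "flat") else "firth")
            estimates[model.param_names[0]] = {
                "value": fit.value, "se": fit.standard_error,
                "equation": fit.equation}
    except (ImproperPosteriorError, DivergenceError) as exc:
        error = {"type": type(exc).__name__, "message": str(exc),
                 "guidance": "use prior_kind='median' (or 'firth') to obtain "
                             "a proper pseudo-posterior under monotone likelihood"}

    record = ResultRecord(config=config.to_dict(), config_hash=config.digest(),
                          version=__version__, timestamp=time.time(),
                          estimates=estimates, evalues=evalues,
                          map_estimate=map_estimate, hpd=hpd,
                          warnings=warnings, error=error)
    if config.out:
        record.to_json(config.out)
    return record


# --------------------------------------------------------------------------
# skew-normal prior utilities (shared by the harnesses)
# --------------------------------------------------------------------------

_PRIOR_SPLINE_CACHE: dict = {}


def skewnormal_logprior(kind: str, bounds: tuple[float, float] = (-5.0, 25.0),
                        points: int = 121):
    """log prior for the skew-normal shape on a grid, splined.

    kind ∈ {flat, median, firth, jeffreys}; improper kinds are truncated to
    ``bounds`` when used as sampling priors.  The spline is data-independent
    and memoized (each node costs several quadratures).
    """
    key = (kind, bounds, points)
    if key not in _PRIOR_SPLINE_CACHE:
        model = SkewNormalShape()
        grid = np.linspace(bounds[0], bounds[1], points)
        logp = corrections.matching_logprior_scalar(model, {
            "flat": "none", "median": "median", "firth": "firth",
            "jeffreys": "jeffreys"}[kind], grid)
        _PRIOR_SPLINE_CACHE[key] = interpolate.CubicSpline(grid, logp)
    spline = _PRIOR_SPLINE_CACHE[key]
    return lambda th: spline(np.clip(th, bounds[0], bounds[1]))


def _skewnorm_m_spline(kind: str, bounds: tuple[float, float], points: int = 81):
    """Spline of the scalar adjustment m(θ) for the skew-normal shape."""
    model = SkewNormalShape()
    grid = np.linspace(bounds[0], bounds[1], points)
    corr = corrections.make_correction(model, kind)
    vals = np.array([corr(t) for t in grid])
    return interpolate.CubicSpline(grid, vals)


# --------------------------------------------------------------------------
# null calibration (first-order e-value distribution under H0)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class NullCalibrationResult:
    table: pd.DataFrame               # one row per replicate, columns per arm
    ks_distance: dict                 # arm -> KS distance from Uniform(0,1)
    infinite_estimates: int           # flat-prior arm (ev recorded as 0)
    theta0: float
    n: int
    replicates: int
    seed: int


def run_null_calibration(model: ParametricModel | str, theta0: float, n: int,
                         replicates: int, seed: int,
                         prior_kinds: Sequence[str] = ("median", "flat"),
                         approximations: Sequence[str] = ("score", "wald"),
                         ) -> NullCalibrationResult:
    """Sampling distribution of first-order e-values under a true H0.

    For each replicate a sample of size n is drawn at θ0 and, per prior kind,
    Wald-type (centred at the corresponding estimator) and score-type
    e-values for H0: θ = θ0 are computed.  Monotone-likelihood replicates in
    the flat arm have no finite MLE; their e-value is recorded as 0.
    """
    if isinstance(model, str):
        model = _FAMILIES[model](RunConfig(model=model, seed=seed))
    if model.dim != 1:
        raise ValueError("null calibration harness supports scalar models")
    rng = np.random.default_rng(seed)
    lo, hi = model.support[0]
    width = 12.0 / math.sqrt(float(model.expected_info([theta0], n=n)[0, 0]))
    b_lo = theta0 - width if not np.isfinite(lo) else max(theta0 - width, lo + 1e-3)
    b_hi = theta0 + width if not np.isfinite(hi) else min(theta0 + width, hi - 1e-3)

    info0 = float(model.expected_info([theta0], n=n)[0, 0])
    m_splines = {}
    for kind in prior_kinds:
        if kind != "flat":
            m_splines[kind] = _skewnorm_m_spline(kind, (b_lo, b_hi)) \
                if isinstance(model, SkewNormalShape) \
                else corrections.make_correction(model, kind)

    rows = []
    infinite = 0
    for _ in range(replicates):
        sample = model.simulate([theta0], n, rng)
        score0 = float(model.score([theta0], sample)[0])
        row = {}
        for kind in prior_kinds:
            m_at = (lambda th: 0.0) if kind == "flat" else \
                (lambda th, s=m_splines[kind]: float(s(th)))
            if "score" in approximations:
                t0 = score0 + m_at(theta0)
                row[f"{kind}_score"] = 2.0 * stats.norm.sf(abs(t0) / math.sqrt(info0))
            if "wald" in approximations:
                t_eq = lambda th: float(model.score([th], sample)[0]) + m_at(th)
                try:
                    (a, b), _ = corrections._expand_bracket(
                        t_eq, theta0, (lo, hi), scale=1.0 / math.sqrt(info0))
                    est = optimize.brentq(t_eq, a, b, xtol=1e-10)
                    row[f"{kind}_wald"] = 2.0 * stats.norm.sf(
                        abs(theta0 - est) * math.sqrt(info0))
                except DivergenceError:
                    row[f"{kind}_wald"] = 0.0
                    if kind == "flat":
                        infinite += 1
        rows.append(row)
    table = pd.DataFrame(rows)
    ks = {col: float(stats.kstest(table[col].to_numpy(), "uniform").statistic)
          for col in table.columns}
    return NullCalibrationResult(table=table, ks_distance=ks,
                                 infinite_estimates=infinite, theta0=theta0,
                                 n=n, replicates=replicates, seed=seed)


# --------------------------------------------------------------------------
# skew-normal ABC experiment across priors and sample sizes
# --------------------------------------------------------------------------

def run_table1_experiment(seed: int, sizes: Sequence[int] = (20, 30, 50, 200),
                          null_values: Sequence[float] = (3.0, 4.0),
                          priors: Sequence[str] = ("flat", "median", "firth",
                                                   "jeffreys"),
                          theta0: float = 3.0, n_draws: int = 100000,
                          accept_fraction: float = 0.05,
                          prior_bounds: tuple[float, float] = (-5.0, 25.0),
                          summary: str = "score-at-grid") -> pd.DataFrame:
    """Skew-normal e-values across priors via the rejection-ABC pipeline.

    One seeded sample per size at θ0; ABC with the requested prior kinds
    (improper priors truncated to ``prior_bounds``); e-values by the exact
    grid rule on a KDE of the accepted draws.  The default summary is the
    mean score (estimating function) on a θ-grid — far more informative
    about the shape parameter than raw sample quantiles.  Values are
    sample-dependent by design.
    """
    model = SkewNormalShape()
    rng = np.random.default_rng(seed)
    samplers = {kind: pp.grid_prior_sampler(skewnormal_logprior(kind, prior_bounds),
                                            prior_bounds)
                for kind in priors}
    rows = []
    for n in sizes:
        sample = model.simulate([theta0], n, rng)
        for kind in priors:
            abc = pp.abc_posterior(model, samplers[kind], sample,
                                   n_draws=n_draws,
                                   accept_fraction=accept_fraction,
                                   summary=summary,
                                   seed=int(rng.integers(2 ** 31 - 1)))
            acc = abc.accepted_draws
            kde = stats.gaussian_kde(acc, bw_method="silverman")
            grid_x = np.linspace(acc.min() - 1.0, acc.max() + 1.0, 801)
            grid = pp.PosteriorGrid.from_log_density(
                grid_x, np.log(np.maximum(kde(grid_x), 1e-300)))
            row = {"n": n, "prior": kind,
                   "map": pp.map_from_samples(acc)[0]}
            for psi0 in null_values:
                res = ev_mod.evalue_exact_1d(grid, ev_mod.Hypothesis(psi0))
                row[f"ev_H0_{psi0:g}"] = res.ev
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fixture generators
# --------------------------------------------------------------------------

def generate_fixture(name: str, seed: int,
                     out_path: Optional[str | Path] = None) -> Dataset:
    """Seeded synthetic datasets for the worked examples.

    ``logistic-separated`` mimics the structure of the endometrial cancer
    grade study: 79 patients, a binary risk factor whose positive stratum
    shows only positive responses (quasi-complete separation) and two
    continuous covariates.
    """
    rng = np.random.default_rng(seed)
    if name == "skewnormal-basic":
        data = SkewNormalShape().simulate([3.0], 20, rng)
    elif name == "skewnormal-allpositive":
        model = SkewNormalShape()
        for _ in range(1000):
            data = model.simulate([3.0], 20, rng)
            if np.all(data.y > 0):
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to draw an all-positive sample")
    elif name == "bivariate-regression":
        theta = np.array([0.5, 1.0, -0.5, 1.0, 0.95])
        data = BivariateRegression().simulate(theta, 20, rng)
        data.provenance["theta"] = theta.tolist()
    elif name == "logistic-separated":
        n = 79
        nv = (np.arange(n) < 13).astype(float)
        pi = np.round(rng.uniform(0.5, 4.0, n), 3)
        eh = np.round(rng.uniform(0.5, 3.5, n), 3)
        eta = 1.0 - 1.6 * eh + 0.1 * pi
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        y[nv == 1.0] = 1.0  # quasi-complete separation in the NV stratum
        frame = pd.DataFrame({"y": y, "nv": nv, "pi": pi, "eh": eh})
        data = Dataset(frame, response="y", covariates=("nv", "pi", "eh"),
                       provenance={"kind": "synthetic",
                                   "generator": "logistic-separated"})
    else:
        raise ValueError(f"unknown fixture {name!r}")
    data.provenance.update({"kind": "synthetic", "generator-id": name,
                            "seed": seed})
    if out_path is not None:
        out_path = Path(out_path)
        data.to_csv(out_path)
        sidecar = out_path.with_suffix(".json")
        sidecar.write_text(json.dumps(data.provenance, indent=2))
    return data


def load_endometrial(path) -> tuple[Dataset, LogisticRegression]:
    """Load a user-supplied endometrial cancer grade CSV (HG, NV, PI, EH).

    The dataset itself is not distributed with this package; any CSV with
    those four columns is accepted.
    """
    frame = pd.read_csv(path)
    required = {"HG", "NV", "PI", "EH"}
    if not required.issubset(frame.columns):
        raise ValueError(f"endometrial CSV must contain columns {sorted(required)}")
    data = Dataset(frame[["HG", "NV", "PI", "EH"]], response="HG",
                   covariates=("NV", "PI", "EH"),
                   provenance={"kind": "file", "path": str(path)})
    model = LogisticRegression(covariates=("NV", "PI", "EH"), interest="NV",
                               response="HG")
    return data, model
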