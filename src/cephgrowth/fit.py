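"""Bayesian fits of the double-logistic growth model.

Two model variants are fit with the same priors:

* **longitudinal** — the multilevel reference model: each observation
  ``y_i ~ Normal(mu_i, sigma)`` with ``mu_i`` the double-logistic curve at
  the observation age plus an individual random intercept
  ``a_j ~ Normal(0, sigma_id)``. Because both the intercept and the
  residual are Gaussian, the intercepts are integrated out analytically:
  an individual's observation vector is multivariate normal with
  covariance ``sigma^2 I + sigma_id^2 J``, whose log-density has a cheap
  closed form via the rank-one Woodbury identity. The sampler therefore
  explores only the eight population-level parameters
  (f, a1, b1, c1, b2, c2, sigma, sigma_id); per-individual intercept draws
  are recovered afterwards by exact conditional Normal sampling, so the
  joint draws are from the full hierarchical posterior.
* **cross-sectional** — the same curve and priors without the intercept
  term: a single observation per individual, residual SD ``sigma`` only.
  Under this model phenotypic variation and measurement error are
  confounded, so its ``sigma`` estimates the total apparent SD
  ``sqrt(sigma^2 + sigma_id^2)``.

Posterior sampling uses an affine-invariant ensemble sampler; walkers are
grouped into the configured number of chains for rank-normalized R-hat and
bulk-ESS diagnostics. A ``map`` mode maximizes the identical log posterior
density (penalized likelihood) for desk-scale resampling runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import expit

from .growth import GrowthParams
from .priors import PriorSpec
from .simulate import LongitudinalDataset

__all__ = [
    "McmcConfig",
    "FitConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "PredictionBands",
    "fit_longitudinal",
    "fit_cross_sectional",
    "posterior_predict",
    "check_convergence",
]

_CURVE_PARAMS = GrowthParams.param_names()  # ("f","a1","b1","c1","b2","c2")


@dataclass(frozen=True)
class McmcConfig:
    """Ensemble-MCMC settings.

    ``iterations`` counts ensemble moves; the first ``warmup_frac`` of them
    is discarded. ``chains * walkers_per_chain`` walkers run as one
    ensemble and are grouped into ``chains`` pseudo-chains for diagnostics.
    Starting values are drawn from the priors separately for every walker.
    """

    chains: int = 4
    iterations: int = 10_000
    warmup_frac: float = 0.5
    walkers_per_chain: int = 8
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.walkers_per_chain < 1:
            raise ValueError("chains and walkers_per_chain must be >= 1")
        if not 0.0 < self.warmup_frac < 1.0:
            raise ValueError("warmup_frac must be in (0, 1)")
        if self.iterations < 10:
            raise ValueError("iterations too small")


@dataclass(frozen=True)
class FitConfig:
    """How to fit a model: full MCMC or a MAP point estimate."""

    mode: str = "mcmc"  # "mcmc" | "map"
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("mcmc", "map"):
            raise ValueError(f"unknown fit mode {self.mode!r}")


@dataclass
class PosteriorSamples:
    """Posterior draws (or a MAP point mass) for one fitted model.

    ``draws`` maps parameter name to an array of shape (chains, draws);
    ``"a_id"`` (longitudinal only) has shape (chains, draws, n_individuals).
    In ``map`` mode there is a single chain with a single draw.
    """

    draws: dict[str, np.ndarray]
    mode: str                      # "mcmc" | "map"
    model: str                     # "longitudinal" | "cross_sectional"
    n_warmup: int = 0
    flags: tuple[str, ...] = ()
    individual_ids: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return self.draws["f"].shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.draws["f"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def median_params(self) -> GrowthParams:
        """Parameter-wise posterior medians as a growth-parameter set."""
        return GrowthParams(**{k: float(np.median(self.flat(k))) for k in _CURVE_PARAMS})

    def to_frame(self) -> pd.DataFrame:
        """Scalar draws as a tidy table (chain, iteration, parameters)."""
        names = [k for k, v in self.draws.items() if v.ndim == 2]
        nc, nd = self.n_chains, self.n_draws_per_chain
        out = {
            "chain": np.repeat(np.arange(nc), nd),
            "iteration": np.tile(np.arange(nd), nc),
        }
        for k in names:
            out[k] = self.draws[k].reshape(-1)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class ConvergenceReport:
    """Rank-normalized split R-hat and bulk ESS per parameter.

    ``passed`` requires every R-hat < 1.01 and every ESS >= 400.
    """

    rhat: dict[str, float]
    ess: dict[str, float]
    passed: bool


@dataclass(frozen=True)
class PredictionBands:
    """Median curve plus central quantile bands on an age grid."""

    age_grid: np.ndarray
    median: np.ndarray
    lower: dict[int, np.ndarray]
    upper: dict[int, np.ndarray]
    levels: tuple[int, ...]
    target: str


# ---------------------------------------------------------------------------
# log densities
# ---------------------------------------------------------------------------

def _curve(ages: np.ndarray, theta: np.ndarray) -> np.ndarray:
    f, a1, b1, c1, b2, c2 = theta[:6]
    return a1 * expit(b1 * (ages - c1)) + (f - a1) * expit(b2 * (ages - c2))


def log_prior(theta: np.ndarray, prior: PriorSpec, hierarchical: bool) -> float:
    """Joint log prior at theta = (f, a1, b1, c1, b2, c2, sigma[, sigma_id]).

    Normal priors with the fixed spreads, rates truncated at zero,
    Exponential(0.25) on the scale parameters. Truncation constants are
    omitted (they do not depend on theta).
    """
    f, a1, b1, c1, b2, c2 = theta[:6]
    sigma = theta[6]
    if b1 <= 0 or b2 <= 0 or sigma <= 0 or f <= 0 or a1 < 0:
        return -np.inf
    lp = 0.0
    for val, name in zip((f, a1, b1, c1, b2, c2), _CURVE_PARAMS):
        mu, sd = getattr(prior.means, name), prior.sds[name]
        lp += -0.5 * ((val - mu) / sd) ** 2 - math.log(sd)
    rate = prior.exp_rates["sigma"]
    lp += math.log(rate) - rate * sigma
    if hierarchical:
        sigma_id = theta[7]
        if sigma_id <= 0:
            return -np.inf
        rate = prior.exp_rates["sigma_id"]
        lp += math.log(rate) - rate * sigma_id
    return lp


def loglik_cross_sectional(theta: np.ndarray, ages: np.ndarray, values: np.ndarray) -> float:
    sigma = theta[6]
    if sigma <= 0:
        return -np.inf
    resid = values - _curve(ages, theta)
    n = ages.size
    return -0.5 * (resid @ resid) / sigma**2 - n * math.log(sigma) - 0.5 * n * math.log(2 * math.pi)


def loglik_longitudinal(
    theta: np.ndarray,
    ages: np.ndarray,
    values: np.ndarray,
    idx: np.ndarray,
    n_per_id: np.ndarray,
) -> float:
    """Marginal log likelihood with individual intercepts integrated out.

    Per individual the covariance is ``sigma^2 I + sigma_id^2 J``; its
    determinant and inverse follow from the rank-one update, so the whole
    likelihood costs one pass over the observations.
    """
    sigma, sigma_id = theta[6], theta[7]
    if sigma <= 0 or sigma_id <= 0:
        return -np.inf
    resid = values - _curve(ages, theta)
    s2, t2 = sigma**2, sigma_id**2
    sum_r = np.bincount(idx, weights=resid, minlength=n_per_id.size)
    sum_r2 = np.bincount(idx, weights=resid * resid, minlength=n_per_id.size)
    denom = s2 + n_per_id * t2
    quad = (sum_r2 - (t2 / denom) * sum_r**2) / s2
    logdet = (n_per_id - 1) * math.log(s2) + np.log(denom)
    n = ages.size
    return -0.5 * float(np.sum(quad + logdet)) - 0.5 * n * math.log(2 * math.pi)


def log_posterior_longitudinal(theta, prior, ages, values, idx, n_per_id) -> float:
    lp = log_prior(theta, prior, hierarchical=True)
    if not np.isfinite(lp):
        return -np.inf
    return lp + loglik_longitudinal(theta, ages, values, idx, n_per_id)


def log_posterior_cross_sectional(theta, prior, ages, values) -> float:
    lp = log_prior(theta, prior, hierarchical=False)
    if not np.isfinite(lp):
        return -np.inf
    return lp + loglik_cross_sectional(theta, ages, values)


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------

def _pack(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    codes, uniques = pd.factorize(table["individual_id"])
    ages = table["age"].to_numpy(dtype=float)
    values = table["value"].to_numpy(dtype=float)
    n_per_id = np.bincount(codes)
    return ages, values, codes, n_per_id.astype(float), list(uniques)


def _init_theta(prior: PriorSpec, rng: np.random.Generator, hierarchical: bool) -> np.ndarray:
    p = prior.sample_params(rng)
    theta = [p.f, p.a1, p.b1, p.c1, p.b2, p.c2, rng.exponential(1.0 / prior.exp_rates["sigma"])]
    if hierarchical:
        theta.append(rng.exponential(1.0 / prior.exp_rates["sigma_id"]))
    return np.array(theta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _run_ensemble(log_prob, args, ndim, prior, cfg: McmcConfig, hierarchical: bool):
    nwalkers = max(cfg.chains * cfg.walkers_per_chain, 2 * ndim + 2)
    # keep walker count a multiple of the chain count for even grouping
    nwalkers += (-nwalkers) % cfg.chains
    rng = np.random.default_rng(cfg.seed)
    p0 = np.empty((nwalkers, ndim))
    for w in range(nwalkers):
        theta = _init_theta(prior, rng, hierarchical)
        for _ in range(100):
            if np.isfinite(log_prob(theta, *args)):
                break
            theta = _init_theta(prior, rng, hierarchical)
        p0[w] = theta
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, args=args)
    sampler.random_state = np.random.RandomState(cfg.seed).get_state()  # reproducible moves
    sampler.run_mcmc(p0, cfg.iterations, progress=False)
    n_warm = int(cfg.iterations * cfg.warmup_frac)
    chain = sampler.get_chain(discard=n_warm, thin=cfg.thin)  # (steps, walkers, ndim)
    steps = chain.shape[0]
    per_chain = nwalkers // cfg.chains
    # walker w belongs to chain w % chains; concatenate its steps
    grouped = np.empty((cfg.chains, per_chain * steps, ndim))
    for c in range(cfg.chains):
        grouped[c] = chain[:, c::cfg.chains, :].transpose(1, 0, 2).reshape(-1, ndim)
    return grouped, n_warm


def _map_estimate(log_prob, args, prior, hierarchical, theta0=None) -> np.ndarray:
    """Maximize the log posterior density; scales searched in log space."""
    n_scales = 2 if hierarchical else 1

    def unpack(x):
        theta = np.empty(6 + n_scales)
        theta[:6] = x[:6]
        theta[6:] = np.exp(x[6:])
        return theta

    def nlp(x):
        val = log_prob(unpack(x), *args)
        return -val if np.isfinite(val) else 1e12

    if theta0 is None:
        m = prior.means
        theta0 = np.array([m.f, m.a1, m.b1, m.c1, m.b2, m.c2] + [1.0] * n_scales)
    x0 = np.concatenate([theta0[:6], np.log(np.maximum(theta0[6:], 1e-6))])
    lb = np.array([1e-6, 0.0, 1e-4, -50.0, 1e-4, -50.0] + [-14.0] * n_scales)
    ub = np.array([1e4, 1e4, 50.0, 80.0, 50.0, 80.0] + [7.0] * n_scales)
    res = minimize(nlp, x0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10})
    return unpack(res.x), bool(res.success)


def _warm_start(ages, values, prior: PriorSpec) -> np.ndarray:
    """Nonlinear least squares from the prior means, for MAP initialization."""
    m = prior.means
    x0 = np.array([m.f, m.a1, m.b1, m.c1, m.b2, m.c2])
    lo = np.array([1e-6, 0.0, 1e-4, -50.0, 1e-4, -50.0])
    hi = np.array([1e4, 1e4, 50.0, 80.0, 50.0, 80.0])

    def resid(x):
        return values - _curve(ages, x)

    try:
        sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), max_nfev=2000)
        x, r = sol.x, sol.fun
    except Exception:
        x, r = x0, resid(x0)
    s = float(np.std(r))
    return np.concatenate([x, [max(s, 1e-4)]])


def _conditional_intercepts(
    grouped: np.ndarray, ages, values, idx, n_per_id, seed: int, max_draws: int = 200
) -> np.ndarray:
    """Exact conditional Normal draws of the individual intercepts.

    Given theta, a_j | data ~ Normal(m_j, v_j) with
    v_j = 1 / (1/sigma_id^2 + n_j/sigma^2) and v_j * sum(resid_j)/sigma^2
    as mean. Thinned to at most ``max_draws`` per chain to bound memory.
    """
    rng = np.random.default_rng(seed)
    nc, nd, _ = grouped.shape
    stride = max(1, nd // max_draws)
    kept = np.arange(0, nd, stride)
    n_id = n_per_id.size
    out = np.empty((nc, kept.size, n_id))
    for c in range(nc):
        for k, d in enumerate(kept):
            theta = grouped[c, d]
            s2, t2 = theta[6] ** 2, theta[7] ** 2
            resid = values - _curve(ages, theta)
            sum_r = np.bincount(idx, weights=resid, minlength=n_id)
            v = 1.0 / (1.0 / t2 + n_per_id / s2)
            mean = v * sum_r / s2
            out[c, k] = rng.normal(mean, np.sqrt(v))
    return out


_SCALAR_LONG = (*_CURVE_PARAMS, "sigma", "sigma_id")
_SCALAR_CS = (*_CURVE_PARAMS, "sigma")


def fit_longitudinal(
    data: LongitudinalDataset,
    prior: PriorSpec,
    config: FitConfig | McmcConfig | None = None,
) -> PosteriorSamples:
    """Fit the multilevel longitudinal model.

    Every individual must contribute at least two observations. In
    ``mcmc`` mode the full hierarchical posterior is sampled (intercepts
    marginalized during sampling, recovered by conditional draws); in
    ``map`` mode the marginal posterior density is maximized and the
    intercepts are set to their conditional means.
    """
    if isinstance(config, McmcConfig):
        config = FitConfig(mode="mcmc", mcmc=config)
    cfg = config or FitConfig()
    ages, values, idx, n_per_id, ids = _pack(data.table)
    if np.min(n_per_id) < 2:
        raise ValueError("every individual needs >= 2 observations for the longitudinal model")
    args = (prior, ages, values, idx, n_per_id)
    flags: list[str] = []
    if cfg.mode == "map":
        theta0 = _warm_start(ages, values, prior)
        theta0 = np.concatenate([theta0, [1.0]])  # sigma_id start, mm
        theta, ok = _map_estimate(log_posterior_longitudinal, args, prior, True, theta0)
        if not ok:
            flags.append("optimizer-not-converged")
        grouped = theta[None, None, :]
        draws = {k: grouped[:, :, i].copy() for i, k in enumerate(_SCALAR_LONG)}
        s2, t2 = theta[6] ** 2, theta[7] ** 2
        resid = values - _curve(ages, theta)
        sum_r = np.bincount(idx, weights=resid, minlength=n_per_id.size)
        v = 1.0 / (1.0 / t2 + n_per_id / s2)
        draws["a_id"] = (v * sum_r / s2)[None, None, :]
        return PosteriorSamples(draws=draws, mode="map", model="longitudinal",
                                flags=tuple(flags), individual_ids=tuple(ids))
    grouped, n_warm = _run_ensemble(
        log_posterior_longitudinal, args, 8, prior, cfg.mcmc, hierarchical=True
    )
    draws = {k: grouped[:, :, i].copy() for i, k in enumerate(_SCALAR_LONG)}
    draws["a_id"] = _conditional_intercepts(
        grouped, ages, values, idx, n_per_id, seed=cfg.mcmc.seed + 1
    )
    post = PosteriorSamples(draws=draws, mode="mcmc", model="longitudinal",
                            n_warmup=n_warm, individual_ids=tuple(ids))
    report = check_convergence(post)
    if not report.passed:
        post.flags = ("not-converged",)
    return post


def fit_cross_sectional(
    data,
    prior: PriorSpec,
    config: FitConfig | None = None,
) -> PosteriorSamples:
    """Fit the single-level model to one-observation-per-individual data.

    ``data`` is a cross-sectional dataset (or any table with the dataset
    schema) containing exactly one observation per individual and at least
    five observations. ``map`` mode returns the penalized-likelihood point
    estimate under the identical priors — the workhorse for large
    resampling designs; ``mcmc`` mode samples the posterior.
    """
    cfg = config or FitConfig(mode="map")
    table = data.table if hasattr(data, "table") else data
    if table["individual_id"].duplicated().any():
        raise ValueError("cross-sectional data must have one observation per individual")
    n = len(table)
    if n < 5:
        raise ValueError(f"cross-sectional fit needs n >= 5 observations, got {n}")
    flags: list[str] = []
    if n < 10:
        flags.append("usable-with-caution")
    ages = table["age"].to_numpy(dtype=float)
    values = table["value"].to_numpy(dtype=float)
    args = (prior, ages, values)
    if cfg.mode == "map":
        theta0 = _warm_start(ages, values, prior)
        theta, ok = _map_estimate(log_posterior_cross_sectional, args, prior, False, theta0)
        if not ok:
            flags.append("optimizer-not-converged")
        grouped = theta[None, None, :]
        draws = {k: grouped[:, :, i].copy() for i, k in enumerate(_SCALAR_CS)}
        return PosteriorSamples(draws=draws, mode="map", model="cross_sectional",
                                flags=tuple(flags))
    grouped, n_warm = _run_ensemble(
        log_posterior_cross_sectional, args, 7, prior, cfg.mcmc, hierarchical=False
    )
    draws = {k: grouped[:, :, i].copy() for i, k in enumerate(_SCALAR_CS)}
    post = PosteriorSamples(draws=draws, mode="mcmc", model="cross_sectional",
                            n_warmup=n_warm, flags=tuple(flags))
    report = check_convergence(post)
    if not report.passed:
        post.flags = post.flags + ("not-converged",)
    return post


# ---------------------------------------------------------------------------
# prediction and diagnostics
# ---------------------------------------------------------------------------

def _curves_from_draws(draws: dict[str, np.ndarray], grid: np.ndarray) -> np.ndarray:
    """(n_total_draws, n_grid) curve matrix, vectorized over draws."""
    f = draws["f"].reshape(-1, 1)
    a1 = draws["a1"].reshape(-1, 1)
    b1 = draws["b1"].reshape(-1, 1)
    c1 = draws["c1"].reshape(-1, 1)
    b2 = draws["b2"].reshape(-1, 1)
    c2 = draws["c2"].reshape(-1, 1)
    g = grid[None, :]
    return a1 * expit(b1 * (g - c1)) + (f - a1) * expit(b2 * (g - c2))


def posterior_predict(
    post: PosteriorSamples,
    age_grid,
    levels: tuple[int, ...] = (50, 80, 98),
    target: str = "mean-curve",
    seed: int = 0,
    min_noise_draws: int = 2000,
) -> PredictionBands:
    """Central posterior quantile bands of trait size across age.

    ``mean-curve`` bands summarize uncertainty in the population curve
    itself; ``new-observation`` bands add per-draw Normal(0, sigma)
    measurement noise — and Normal(0, sigma_id) for an unseen individual
    when the posterior comes from the longitudinal model — giving the
    age-specific range in which a stated fraction of new measurements is
    expected (the growth-standard intervals). A MAP posterior is a point
    mass: its mean-curve bands collapse onto the fitted curve, while
    new-observation bands reflect the fitted noise SDs.
    """
    for lev in levels:
        if not 0 < lev < 100:
            raise ValueError(f"band level {lev} outside (0, 100)")
    if target not in ("mean-curve", "new-observation"):
        raise ValueError(f"unknown prediction target {target!r}")
    grid = np.asarray(age_grid, dtype=float)
    curves = _curves_from_draws(post.draws, grid)
    if target == "new-observation":
        rng = np.random.default_rng(seed)
        sigma = post.flat("sigma")
        if post.model == "longitudinal":
            sigma = np.sqrt(sigma**2 + post.flat("sigma_id") ** 2)
        if curves.shape[0] < min_noise_draws:
            reps = int(np.ceil(min_noise_draws / curves.shape[0]))
            curves = np.tile(curves, (reps, 1))
            sigma = np.tile(sigma, reps)
        curves = curves + rng.normal(size=curves.shape) * sigma[:, None]
    median = np.median(curves, axis=0)
    lower: dict[int, np.ndarray] = {}
    upper: dict[int, np.ndarray] = {}
    for lev in levels:
        alpha = (100 - lev) / 200.0
        lower[lev] = np.quantile(curves, alpha, axis=0)
        upper[lev] = np.quantile(curves, 1 - alpha, axis=0)
    return PredictionBands(age_grid=grid, median=median, lower=lower, upper=upper,
                           levels=tuple(levels), target=target)


def check_convergence(post: PosteriorSamples, rhat_max: float = 1.01, ess_min: float = 400.0) -> ConvergenceReport:
    """Rank-normalized split R-hat and bulk ESS for every scalar parameter."""
    if post.mode != "mcmc":
        raise ValueError("convergence diagnostics require an MCMC posterior")
    if post.n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    scalars = {k: v for k, v in post.draws.items() if v.ndim == 2}
    idata = az.from_dict(posterior=scalars)
    rhat_ds = az.rhat(idata, method="rank")
    ess_ds = az.ess(idata, method="bulk")
    rhat = {k: float(rhat_ds[k].values) for k in scalars}
    ess = {k: float(ess_ds[k].values) for k in scalars}
    passed = all(r < rhat_max for r in rhat.values()) and all(e >= ess_min for e in ess.values())
    return ConvergenceReport(rhat=rhat, ess=ess, passed=passed)
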