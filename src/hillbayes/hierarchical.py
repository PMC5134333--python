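"""Hierarchical (multi-level) model of inter-experiment variability.

Each experiment i = 1..Ne has its own potency and steepness,

    Hill_i  ~ log-logistic(alpha, beta)        (scale alpha > 0, shape beta)
    pIC50_i ~ logistic(mu, s)                  (location mu, scale s > 0)
    y_ij    ~ TruncNormal(f(x_ij; pIC50_i, Hill_i), sigma^2; [0, 100]),

with a single observation-noise SD sigma shared across experiments.  The
log-logistic density used throughout (scale-shape form, median alpha) is

    p(h; alpha, beta) = (beta/alpha) (h/alpha)^(beta-1) / (1 + (h/alpha)^beta)^2,

equivalently: log(h) follows a logistic distribution with location log(alpha)
and scale 1/beta.  alpha is therefore the typical (median) Hill coefficient
and mu the typical pIC50, which is what the "underlying effect" prediction
mode reads off directly.

Top-level parameters (alpha, beta, mu, s, sigma) get gamma hyperpriors (mu's
shifted down to -4 so it can go slightly negative but keeps little mass below
-2), with hard support constraints beta > 2 (no density mass or gradient at
Hill = 0) and sigma > 1e-3 (observation error never vanishes).

The posterior predictive for a future experiment's Hill or pIC50 is the
equal-weight mixture over retained MCMC iterations t = 1..T of the
per-iteration population densities; sampling from it goes through the
averaged CDF by inverse transform on a fine monotone grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from .core import hill_response
from .dataset import DoseResponseDataset
from .single_level import truncnorm_loglik

__all__ = [
    "TopLevelParams",
    "GammaSpec",
    "HierPriorConfig",
    "PredictiveDistribution",
    "logistic_logpdf",
    "logistic_cdf",
    "loglogistic_logpdf",
    "loglogistic_cdf",
    "log_hyperprior",
    "log_posterior_hier",
    "posterior_predictive",
    "sample_predictive",
]

BETA_FLOOR = 2.0      # log-logistic shape: zero density and slope at Hill=0
SIGMA_FLOOR = 1e-3    # % block; observation error never exactly zero


@dataclass(frozen=True)
class TopLevelParams:
    """Population ('top-level') parameters of the hierarchical model."""

    alpha: float   # log-logistic scale = median Hill
    beta: float    # log-logistic shape (> 2)
    mu: float      # logistic location = typical pIC50, log(Molar)
    s: float       # logistic scale, log(Molar)
    sigma: float   # shared observation noise SD, % block (> 1e-3)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.mu, self.s, self.sigma])


def logistic_logpdf(p, mu, s):
    """Log density of the logistic distribution with location mu, scale s.

    Stable form: -|z| - 2*log1p(exp(-|z|)) - log(s) with z = (p - mu)/s.
    """
    p = np.asarray(p, dtype=float)
    if np.any(np.asarray(s) <= 0):
        raise ValueError("logistic scale s must be strictly positive")
    z = np.abs((p - mu) / s)
    out = -z - 2.0 * np.log1p(np.exp(-z)) - np.log(s)
    return out if out.ndim else float(out)


def logistic_cdf(p, mu, s):
    return expit((np.asarray(p, dtype=float) - mu) / s)


def loglogistic_logpdf(h, alpha, beta):
    """Log density of the log-logistic distribution, scale alpha, shape beta.

    -inf for h <= 0 (the support edge), ValueError for non-positive alpha
    or beta.  Uses z = beta*log(h/alpha):
    log p = log(beta) - log(h) - |z| - 2*log1p(exp(-|z|)).
    """
    h = np.asarray(h, dtype=float)
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(beta) <= 0):
        raise ValueError("log-logistic alpha and beta must be strictly positive")
    out = np.full(np.broadcast_shapes(h.shape, np.shape(alpha), np.shape(beta)),
                  -np.inf)
    pos = np.broadcast_to(h > 0, out.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        logh = np.log(np.where(h > 0, h, 1.0))
        z = np.abs(np.asarray(beta) * (logh - np.log(alpha)))
        val = np.log(beta) - logh - z - 2.0 * np.log1p(np.exp(-z))
    out[pos] = np.broadcast_to(val, out.shape)[pos]
    return out if out.ndim else float(out)


def loglogistic_cdf(h, alpha, beta):
    """CDF 1 / (1 + (h/alpha)^(-beta)); alpha is the median."""
    h = np.asarray(h, dtype=float)
    with np.errstate(divide="ignore"):
        logh = np.log(np.where(h > 0, h, np.nan))
    out = np.where(h > 0, expit(np.asarray(beta) * (logh - np.log(alpha))), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GammaSpec:
    """Shape/scale gamma prior, optionally shifted along the x-axis."""

    shape: float
    scale: float
    shift: float = 0.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    def logpdf(self, x) -> float:
        return gamma_dist.logpdf(x, a=self.shape, scale=self.scale, loc=self.shift)

    def cdf(self, x) -> float:
        return gamma_dist.cdf(x, a=self.shape, scale=self.scale, loc=self.shift)

    def mean(self) -> float:
        return self.shape * self.scale + self.shift


@dataclass(frozen=True)
class HierPriorConfig:
    """Gamma hyperpriors on the top-level parameters.

    The defaults are broad: they cover the Hill-coefficient and pIC50
    population-parameter ranges reported for large ion-channel screening
    repeats (alpha near 1, beta of a few, s well below 1, sigma a few % with
    generous headroom), while mu's prior is shifted down to -4 so that
    essentially no mass (< 5%) sits below -2, where dose-response curves are
    flat over any practical concentration range.  Every field is replaceable
    for screens with different characteristics.
    """

    alpha: GammaSpec = field(default_factory=lambda: GammaSpec(2.5, 0.5))
    beta: GammaSpec = field(default_factory=lambda: GammaSpec(2.5, 2.5))
    mu: GammaSpec = field(default_factory=lambda: GammaSpec(7.5, 1.5, shift=-4.0))
    s: GammaSpec = field(default_factory=lambda: GammaSpec(2.0, 0.5))
    sigma: GammaSpec = field(default_factory=lambda: GammaSpec(2.0, 3.5))


def log_hyperprior(top: TopLevelParams, config: HierPriorConfig | None = None) -> float:
    """Sum of gamma log prior densities over the top-level parameters.

    Returns -inf if beta <= 2, sigma <= 1e-3, or any component falls outside
    its gamma support; these hard bounds act as proposal rejection in MCMC.
    """
    config = config or HierPriorConfig()
    if top.beta <= BETA_FLOOR or top.sigma <= SIGMA_FLOOR:
        return -np.inf
    total = (
        config.alpha.logpdf(top.alpha)
        + config.beta.logpdf(top.beta)
        + config.mu.logpdf(top.mu)
        + config.s.logpdf(top.s)
        + config.sigma.logpdf(top.sigma)
    )
    return float(total) if np.isfinite(total) else -np.inf


def log_posterior_hier(
    data: DoseResponseDataset,
    top: TopLevelParams,
    pic50_i: np.ndarray,
    hill_i: np.ndarray,
    config: HierPriorConfig | None = None,
) -> float:
    """Unnormalised joint log posterior of the hierarchical model.

    ``pic50_i`` and ``hill_i`` hold the per-experiment parameters in sorted
    experiment-label order; their length must equal ``data.n_experiments``.
    The free parameter vector has dimension 5 + 2*Ne.
    """
    pic50_i = np.asarray(pic50_i, dtype=float)
    hill_i = np.asarray(hill_i, dtype=float)
    ne = data.n_experiments
    if pic50_i.shape != (ne,) or hill_i.shape != (ne,):
        raise ValueError(
            f"need exactly one (pIC50_i, Hill_i) pair per experiment ({ne})"
        )
    lp = log_hyperprior(top, config)
    if not np.isfinite(lp):
        return -np.inf
    if np.any(hill_i <= 0):
        return -np.inf
    lp += float(np.sum(loglogistic_logpdf(hill_i, top.alpha, top.beta)))
    lp += float(np.sum(logistic_logpdf(pic50_i, top.mu, top.s)))
    if not np.isfinite(lp):
        return -np.inf
    for k, (label, doses, responses) in enumerate(data.by_experiment()):
        f = hill_response(doses, pic50_i[k], hill_i[k])
        lp += float(np.sum(truncnorm_loglik(responses, f, top.sigma)))
    return lp if np.isfinite(lp) else -np.inf


class PredictiveDistribution:
    """Equal-weight mixture of per-iteration population distributions.

    For ``family='logistic'`` the components are (mu_t, s_t) pairs; for
    ``family='log-logistic'`` they are (alpha_t, beta_t).  Density and CDF
    are pointwise averages over the T components; inverse-CDF sampling uses
    a deterministic 4096-point monotone grid spanning the 1e-6 .. 1-1e-6
    quantile range of the component envelope.
    """

    GRID_SIZE = 4096
    TAIL = 1e-6

    def __init__(self, family: str, loc: np.ndarray, scale: np.ndarray):
        if family not in ("logistic", "log-logistic"):
            raise ValueError("family must be 'logistic' or 'log-logistic'")
        loc = np.atleast_1d(np.asarray(loc, dtype=float))
        scale = np.atleast_1d(np.asarray(scale, dtype=float))
        if loc.size == 0 or loc.shape != scale.shape:
            raise ValueError("need T >= 1 matching component parameter arrays")
        self.family = family
        self.loc = loc          # mu_t or alpha_t
        self.scale = scale      # s_t  or beta_t
        self.n_components = loc.size
        self._grid = None

    def _component_quantile(self, q: float) -> np.ndarray:
        logit = np.log(q / (1.0 - q))
        if self.family == "logistic":
            return self.loc + self.scale * logit
        return self.loc * np.exp(logit / self.scale)

    def pdf(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for chunk in _chunks(self.n_components):
            if self.family == "logistic":
                lp = logistic_logpdf(
                    x[:, None], self.loc[chunk][None, :], self.scale[chunk][None, :]
                )
            else:
                lp = loglogistic_logpdf(
                    x[:, None], self.loc[chunk][None, :], self.scale[chunk][None, :]
                )
            out += np.exp(lp).sum(axis=1)
        out /= self.n_components
        return out if out.size > 1 else float(out[0])

    def cdf(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for chunk in _chunks(self.n_components):
            if self.family == "logistic":
                c = logistic_cdf(
                    x[:, None], self.loc[chunk][None, :], self.scale[chunk][None, :]
                )
            else:
                c = loglogistic_cdf(
                    x[:, None], self.loc[chunk][None, :], self.scale[chunk][None, :]
                )
            out += c.sum(axis=1)
        out /= self.n_components
        return out if out.size > 1 else float(out[0])

    def _inversion_grid(self):
        if self._grid is None:
            lo = float(np.min(self._component_quantile(self.TAIL)))
            hi = float(np.max(self._component_quantile(1.0 - self.TAIL)))
            if self.family == "log-logistic":
                xs = np.geomspace(max(lo, 1e-300), hi, self.GRID_SIZE)
            else:
                xs = np.linspace(lo, hi, self.GRID_SIZE)
            cdf = np.maximum.accumulate(self.cdf(xs))
            self._grid = (xs, cdf)
        return self._grid

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n values by inverse transform through the averaged CDF."""
        if n < 1:
            raise ValueError("n must be >= 1")
        xs, cdf = self._inversion_grid()
        u = rng.uniform(cdf[0], cdf[-1], size=n)
        return np.interp(u, cdf, xs)


def _chunks(n: int, size: int = 512):
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))


def posterior_predictive(
    loc_samples: np.ndarray, scale_samples: np.ndarray, which: str
) -> PredictiveDistribution:
    """Build the posterior predictive for a future experiment's parameter.

    ``which='Hill'`` expects (alpha_t, beta_t) samples and returns a
    log-logistic mixture; ``which='pIC50'`` expects (mu_t, s_t) samples and
    returns a logistic mixture.
    """
    if which == "Hill":
        return PredictiveDistribution("log-logistic", loc_samples, scale_samples)
    if which == "pIC50":
        return PredictiveDistribution("logistic", loc_samples, scale_samples)
    raise ValueError("which must be 'Hill' or 'pIC50'")


def sample_predictive(
    dist: PredictiveDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Reproducible draws from a predictive mixture (see its ``sample``)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.sample(n, rng)
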