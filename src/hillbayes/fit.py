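"""End-to-end fitting pipelines: CMA-ES start -> adaptive MH -> burn-in.

Both pipelines build a fast closed-over log-posterior (algebraically the
same quantity as ``single_level.log_posterior_single`` /
``hierarchical.log_posterior_hier``, with per-record bookkeeping
precomputed) so the MCMC loop costs one vectorised evaluation per
iteration.  Equality of the fast closures with the reference functions is
asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, ndtr

from .cmaes import cmaes_start
from .core import hill_response
from .dataset import DoseResponseDataset
from .hierarchical import BETA_FLOOR, SIGMA_FLOOR, HierPriorConfig
from .mcmc import (
    AdaptConfig,
    PosteriorChain,
    adaptive_mh,
    curvature_scales,
    discard_burn_in,
)
from .single_level import UniformPriorBounds

__all__ = [
    "FitSettings",
    "fit_single_level",
    "fit_hierarchical",
    "make_single_level_target",
    "make_hierarchical_target",
    "hierarchical_names",
]

_LN10 = np.log(10.0)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

SINGLE_LEVEL_NAMES = ["pIC50", "Hill", "sigma"]


def hierarchical_names(n_experiments: int) -> list[str]:
    """Column names (alpha, beta, mu, s, sigma, pIC50_1.., Hill_1..)."""
    return (
        ["alpha", "beta", "mu", "s", "sigma"]
        + [f"pIC50_{i}" for i in range(1, n_experiments + 1)]
        + [f"Hill_{i}" for i in range(1, n_experiments + 1)]
    )


@dataclass(frozen=True)
class FitSettings:
    """Shared configuration of both pipelines.

    The default chain length matches routine production use (500k
    iterations, quarter burn-in); tests and quick exploration shorten it.
    """

    n_iter: int = 500_000
    burn_fraction: float = 0.25
    seed: int = 1
    prior_bounds: UniformPriorBounds | None = None     # single-level
    prior_config: HierPriorConfig | None = None        # hierarchical
    adapt: AdaptConfig | None = None


def _log_trunc_mass(f, sigma):
    return np.log(ndtr((100.0 - f) / sigma) - ndtr(-f / sigma))


def make_single_level_target(
    data: DoseResponseDataset, bounds: UniformPriorBounds | None = None
):
    """Return (log-posterior closure, parameter bounds array)."""
    bounds = bounds or UniformPriorBounds()
    with np.errstate(divide="ignore"):
        log10x = np.log10(data.doses)
    y = data.responses
    prior_const = bounds.log_density
    box = np.array([bounds.pic50, bounds.hill, bounds.sigma], dtype=float)

    def target(theta: np.ndarray) -> float:
        pic50, hill, sigma = theta
        if not (
            box[0, 0] < pic50 < box[0, 1]
            and box[1, 0] < hill < box[1, 1]
            and box[2, 0] < sigma < box[2, 1]
        ):
            return -np.inf
        f = 100.0 * expit(hill * _LN10 * (log10x - (6.0 - pic50)))
        z = (y - f) / sigma
        ll = np.sum(-0.5 * z * z - _log_trunc_mass(f, sigma))
        return float(ll) - y.size * (np.log(sigma) + _LOG_SQRT_2PI) + prior_const

    return target, box


def make_hierarchical_target(
    data: DoseResponseDataset, config: HierPriorConfig | None = None
):
    """Return (log-posterior closure, bounds array, names) for the joint model.

    Parameter layout: [alpha, beta, mu, s, sigma, pIC50_1..Ne, Hill_1..Ne],
    dimension 5 + 2*Ne.
    """
    config = config or HierPriorConfig()
    ne = data.n_experiments
    labels = data.experiment_labels
    slot = {int(lab): k for k, lab in enumerate(labels)}
    idx = np.array([slot[int(lab)] for lab in data.experiment_ids])
    with np.errstate(divide="ignore"):
        log10x = np.log10(data.doses)
    y = data.responses

    gammas = [config.alpha, config.beta, config.mu, config.s, config.sigma]
    g_shape = np.array([g.shape for g in gammas])
    g_scale = np.array([g.scale for g in gammas])
    g_shift = np.array([g.shift for g in gammas])
    g_const = -gammaln(g_shape) - g_shape * np.log(g_scale)

    # support: gamma lower edges, with the hard floors beta > 2, sigma > 1e-3
    lo5 = g_shift.copy()
    lo5[1] = max(lo5[1], BETA_FLOOR)
    lo5[4] = max(lo5[4], SIGMA_FLOOR)
    lo = np.concatenate([lo5, np.full(ne, -np.inf), np.zeros(ne)])
    hi = np.full(5 + 2 * ne, np.inf)
    bounds = np.column_stack([lo, hi])

    def target(theta: np.ndarray) -> float:
        top = theta[:5]
        pic50_i = theta[5 : 5 + ne]
        hill_i = theta[5 + ne :]
        if np.any(top <= lo[:5]) or np.any(hill_i <= 0.0):
            return -np.inf
        alpha, beta, mu, s, sigma = top
        # gamma hyperpriors (mu evaluated at mu - shift = mu + 4)
        u = top - g_shift
        lp = float(np.sum((g_shape - 1.0) * np.log(u) - u / g_scale + g_const))
        # population terms
        zp = np.abs((pic50_i - mu) / s)
        lp += float(np.sum(-zp - 2.0 * np.log1p(np.exp(-zp)))) - ne * np.log(s)
        logh = np.log(hill_i)
        zh = np.abs(beta * (logh - np.log(alpha)))
        lp += float(
            np.sum(-zh - 2.0 * np.log1p(np.exp(-zh)) - logh)
        ) + ne * np.log(beta)
        # truncated-normal likelihood, all records at once
        f = 100.0 * expit(hill_i[idx] * _LN10 * (log10x - (6.0 - pic50_i[idx])))
        z = (y - f) / sigma
        lp += float(np.sum(-0.5 * z * z - _log_trunc_mass(f, sigma)))
        lp -= y.size * (np.log(sigma) + _LOG_SQRT_2PI)
        return lp if np.isfinite(lp) else -np.inf

    return target, bounds, hierarchical_names(ne)


def _single_level_start(data: DoseResponseDataset) -> np.ndarray:
    """Crude moment-based initial guess handed to CMA-ES."""
    pos = data.doses[data.doses > 0]
    mid = float(np.median(pos)) if pos.size else 1.0
    return np.array([6.0 - np.log10(mid), 1.0, 5.0])


def fit_single_level(
    data: DoseResponseDataset, settings: FitSettings | None = None
) -> PosteriorChain:
    """Pooled fit: 3-parameter chain (pIC50, Hill, sigma) after burn-in."""
    settings = settings or FitSettings()
    target, box = make_single_level_target(data, settings.prior_bounds)
    root = np.random.SeedSequence(settings.seed)
    rng_opt, rng_mh = (np.random.default_rng(s) for s in root.spawn(2))
    start = cmaes_start(target, _single_level_start(data), box, rng_opt)
    widths = box[:, 1] - box[:, 0]
    adapt = settings.adapt or AdaptConfig(
        initial_scales=curvature_scales(target, start, 0.01 * widths)
    )
    chain = adaptive_mh(target, start, settings.n_iter, rng_mh, adapt,
                        names=list(SINGLE_LEVEL_NAMES))
    chain.meta.update(seed=settings.seed, model="single-level",
                      compound=data.compound, channel=data.channel)
    return discard_burn_in(chain, settings.burn_fraction)


def _hierarchical_start(
    data: DoseResponseDataset, rng: np.random.Generator, settings: FitSettings
) -> np.ndarray:
    """Per-experiment CMA-ES fits, then moment-matched top-level start.

    The logistic SD is s*pi/sqrt(3) and log(Hill) has SD pi/(beta*sqrt(3)),
    so sample spreads of the per-experiment estimates convert directly to
    starting values for s and beta.
    """
    est = []
    for label in data.experiment_labels:
        sub = data.experiment(int(label))
        target, box = make_single_level_target(sub, settings.prior_bounds)
        est.append(cmaes_start(target, _single_level_start(sub), box, rng))
    est = np.array(est)
    pic50_i, hill_i = est[:, 0], est[:, 1]
    ne = len(est)

    # noise start from the residuals of the per-experiment start curves;
    # more robust than pooling the per-experiment sigma estimates, any of
    # which can stall on a 4-point experiment
    resid = []
    for k, (label, doses, responses) in enumerate(data.by_experiment()):
        resid.append(responses - hill_response(doses, pic50_i[k], hill_i[k]))
    sigma0 = float(np.clip(np.std(np.concatenate(resid)), 2 * SIGMA_FLOOR, 49.0))

    alpha0 = float(np.clip(np.median(hill_i), 0.05, 20.0))
    spread_logh = float(np.std(np.log(np.maximum(hill_i, 1e-6)))) if ne > 1 else 0.0
    beta0 = (
        float(np.clip(np.pi / (np.sqrt(3.0) * spread_logh), 2.1, 40.0))
        if spread_logh > 1e-3
        else 10.0
    )
    mu0 = float(np.clip(np.median(pic50_i), -3.9, None))
    spread_p = float(np.std(pic50_i)) if ne > 1 else 0.0
    s0 = float(np.clip(spread_p * np.sqrt(3.0) / np.pi, 0.02, 5.0))
    hill_i = np.clip(hill_i, 1e-3, None)
    return np.concatenate([[alpha0, beta0, mu0, s0, sigma0], pic50_i, hill_i])


def fit_hierarchical(
    data: DoseResponseDataset, settings: FitSettings | None = None
) -> PosteriorChain:
    """Joint fit of the hierarchical model; chain dimension 5 + 2*Ne."""
    settings = settings or FitSettings()
    target, bounds, names = make_hierarchical_target(data, settings.prior_config)
    ne = data.n_experiments
    root = np.random.SeedSequence(settings.seed)
    rng_opt, rng_mh = (np.random.default_rng(s) for s in root.spawn(2))

    start = _hierarchical_start(data, rng_opt, settings)
    if not np.isfinite(target(start)):
        # fall back to a generic in-support start
        start = np.concatenate(
            [[1.0, 5.0, 6.0, 0.5, 5.0], np.full(ne, 6.0), np.ones(ne)]
        )
    fallback = np.concatenate(
        [[0.05, 0.5, 0.05, 0.02, 0.1], np.full(ne, 0.05), np.full(ne, 0.05)]
    )
    adapt = settings.adapt or AdaptConfig(
        initial_scales=curvature_scales(target, start, fallback)
    )
    chain = adaptive_mh(target, start, settings.n_iter, rng_mh, adapt, names=names)
    chain.meta.update(seed=settings.seed, model="hierarchical",
                      n_experiments=ne, compound=data.compound,
                      channel=data.channel)
    return discard_burn_in(chain, settings.burn_fraction)
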