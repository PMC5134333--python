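"""Adaptive Metropolis-Hastings sampling and chain handling.

The sampler is a Haario-style adaptive random-walk Metropolis: proposals are
multivariate Normal centred on the current state with covariance

    lambda * ( Cov_hat[chain so far] + eps * I ),

where Cov_hat is the running empirical covariance of the chain and the
global scale lambda starts at the Gelman-Roberts-Gilks optimum 2.38^2 / d
and is nudged by a Robbins-Monro recursion towards a 25% acceptance rate.
The scalar tuning runs from the first iteration; the empirical covariance
replaces the initial diagonal proposal only after a warm-up phase (100*d
iterations by default), so the shape estimate is not dominated by the first
steps.  Proposals falling outside the target's support are rejected via the
target returning -inf, which preserves detailed balance trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, exp, log

import numpy as np

__all__ = [
    "AdaptConfig",
    "PosteriorChain",
    "adaptive_mh",
    "discard_burn_in",
    "curvature_scales",
]


@dataclass(frozen=True)
class AdaptConfig:
    """Tuning knobs of the adaptive proposal.

    ``adapt_start=None`` means 100*d iterations.  ``initial_scales`` sets the
    pre-adaptation diagonal proposal SD per dimension (default: 5% of
    ``max(|start|, 1)`` per coordinate).
    """

    target_accept: float = 0.25
    adapt_start: int | None = None
    adapt_decay: float = 0.6
    cov_jitter: float = 1e-10
    refresh_every: int = 25
    initial_scales: np.ndarray | None = None
    greedy_restart: bool = True


@dataclass
class PosteriorChain:
    """MCMC output: T parameter vectors with log-posterior and accept flags."""

    samples: np.ndarray          # (T, d)
    log_posterior: np.ndarray    # (T,)
    accepted: np.ndarray         # (T,) bool
    names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.samples.ndim != 2 or len(self.samples) != len(self.log_posterior):
            raise ValueError("inconsistent chain arrays")
        if self.samples.shape[1] != len(self.names):
            raise ValueError("one name per parameter column required")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_parameters(self) -> int:
        return self.samples.shape[1]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=self.names)
        df["log_posterior"] = self.log_posterior
        return df

    def summary(self):
        """Posterior mean / median / central 95% interval per parameter."""
        import pandas as pd

        q = np.quantile(self.samples, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {
                "parameter": self.names,
                "mean": self.samples.mean(axis=0),
                "median": q[1],
                "ci_2.5%": q[0],
                "ci_97.5%": q[2],
            }
        )


def adaptive_mh(
    target,
    start,
    n_iter: int,
    seed,
    adapt_config: AdaptConfig | None = None,
    names: list[str] | None = None,
) -> PosteriorChain:
    """Run the adaptive Metropolis-Hastings chain.

    ``target`` is a callable log-density (up to a constant) returning -inf
    outside its support; ``start`` must have finite target value.  The chain
    is fully determined by ``seed`` (an int or a ``numpy.random.Generator``).
    """
    cfg = adapt_config or AdaptConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(start, dtype=float).copy()
    d = x.size
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    lx = float(target(x))
    if not np.isfinite(lx):
        raise ValueError("target is non-finite at the MCMC starting point")

    adapt_start = cfg.adapt_start if cfg.adapt_start is not None else 100 * d
    scales = (
        np.asarray(cfg.initial_scales, dtype=float)
        if cfg.initial_scales is not None
        else 0.05 * np.maximum(np.abs(x), 1.0)
    )
    if scales.shape != (d,) or np.any(scales <= 0):
        raise ValueError("initial_scales must be d positive values")

    log_lambda = log(2.38**2 / d)
    chol = np.diag(scales)          # pre-adaptation proposal Cholesky
    run_mean = x.copy()
    run_m2 = np.zeros((d, d))       # sum of outer deviations (Welford)
    n_seen = 1

    samples = np.empty((n_iter, d))
    logps = np.empty(n_iter)
    accepted = np.empty(n_iter, dtype=bool)
    step = exp(0.5 * log_lambda)
    best_x, best_lx = x.copy(), lx

    # early-phase repositioning checkpoints (geometric, confined to the
    # first fifth of the run, i.e. well inside the default quarter burn-in)
    checkpoints = set()
    if cfg.greedy_restart:
        cp = max(adapt_start, 1)
        while cp < n_iter // 5:
            checkpoints.add(cp)
            cp *= 2
    # a chain in equilibrium sits ~d/2 below the posterior mode; falling an
    # order of magnitude further than that signals a trapped excursion
    stuck_margin = max(2.0 * d, 25.0)

    for t in range(n_iter):
        if t in checkpoints and best_lx - lx > stuck_margin:
            x, lx = best_x.copy(), best_lx
        prop = x + step * (chol @ rng.standard_normal(d))
        lp = float(target(prop))
        log_ratio = lp - lx
        if log_ratio >= 0:
            alpha = 1.0
        else:
            alpha = exp(log_ratio) if log_ratio > -700 else 0.0
        acc = rng.random() < alpha
        if acc:
            x, lx = prop, lp
            if lx > best_lx:
                best_x, best_lx = x.copy(), lx
        samples[t] = x
        logps[t] = lx
        accepted[t] = acc

        # running empirical covariance of the chain
        n_seen += 1
        delta = x - run_mean
        run_mean += delta / n_seen
        run_m2 += np.outer(delta, x - run_mean)

        # global-scale tuning runs from the start; the Robbins-Monro clock
        # restarts when the empirical covariance takes over, so the new
        # proposal shape gets rescaled quickly
        k = (t - adapt_start) if t >= adapt_start else t
        gamma = (k + 1.0) ** (-cfg.adapt_decay)
        log_lambda += gamma * (alpha - cfg.target_accept)
        step = exp(0.5 * log_lambda)
        if t >= adapt_start and (t - adapt_start) % cfg.refresh_every == 0:
            cov = run_m2 / (n_seen - 1) + cfg.cov_jitter * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol = np.diag(np.sqrt(np.diag(cov)))

    return PosteriorChain(
        samples=samples,
        log_posterior=logps,
        accepted=accepted,
        names=names or [f"theta_{i + 1}" for i in range(d)],
        meta={
            "n_iter": n_iter,
            "adapt_start": adapt_start,
            "target_accept": cfg.target_accept,
            "final_proposal_scale": exp(0.5 * log_lambda),
        },
    )


def curvature_scales(target, x0, fallback):
    """Per-dimension proposal SDs from the diagonal curvature of ``target``.

    Central second differences at ``x0`` give -d2 log p / dtheta_i^2; where
    the curvature is positive and finite, 1/sqrt(curvature) approximates the
    local conditional SD and makes a far better initial proposal scale than a
    guess.  Dimensions with unusable curvature fall back to ``fallback``.
    """
    x0 = np.asarray(x0, dtype=float)
    fallback = np.asarray(fallback, dtype=float)
    d = x0.size
    out = np.empty(d)
    f0 = float(target(x0))
    for i in range(d):
        h = max(1e-4, 1e-4 * abs(x0[i]))
        xp = x0.copy()
        xp[i] += h
        xm = x0.copy()
        xm[i] -= h
        curv = -(float(target(xp)) - 2.0 * f0 + float(target(xm))) / h**2
        out[i] = 1.0 / np.sqrt(curv) if (np.isfinite(curv) and curv > 0) else fallback[i]
    return np.clip(out, 1e-4, 10.0 * fallback)


def discard_burn_in(chain: PosteriorChain, fraction: float = 0.25) -> PosteriorChain:
    """Drop the initial ``fraction`` of the chain, keeping ceil((1-f)*T) samples.

    At least one sample is always retained; ``fraction`` must lie in [0, 1).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("burn-in fraction must be in [0, 1)")
    total = len(chain)
    keep = max(1, ceil((1.0 - fraction) * total))
    meta = dict(chain.meta)
    meta.update(burn_in_discarded=total - keep, burn_in_fraction=fraction)
    return PosteriorChain(
        samples=chain.samples[total - keep :].copy(),
        log_posterior=chain.log_posterior[total - keep :].copy(),
        accepted=chain.accepted[total - keep :].copy(),
        names=list(chain.names),
        meta=meta,
    )
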