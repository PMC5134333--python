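"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda)-CMA-ES with
weighted recombination, cumulative step-size adaptation and rank-one plus
rank-mu covariance updates, wrapped in a small restart loop with doubled
population size (the usual remedy for premature convergence on multimodal
or plateau-ridden objectives).  It is used here for one job: finding a good
log-posterior starting point for MCMC, so the implementation favours
robustness and reproducibility over large-scale performance.

Box constraints are handled by evaluating at the point clipped into the
(slightly shrunk) box and adding a quadratic penalty on the violation, a
standard repair-plus-penalty scheme that keeps the fitness landscape smooth
at the boundary.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cmaes_start", "CMAESError"]


class CMAESError(RuntimeError):
    """Raised when no finite objective value can be found."""


def _clip_to_box(x, lower, upper):
    margin = 1e-9 * np.where(np.isfinite(upper - lower), upper - lower, 1.0)
    lo = np.where(np.isfinite(lower), lower + margin, lower)
    hi = np.where(np.isfinite(upper), upper - margin, upper)
    return np.clip(x, lo, hi)


def _run_once(fitness, mean0, sigma0, lam, rng, max_generations, ftol,
              best_f, best_x):
    """One CMA-ES run; returns the updated incumbent (best_f, best_x)."""
    d = mean0.size
    mean = mean0.copy()
    sigma = float(sigma0)

    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cc = (4 + mueff / d) / (d + 4 + 2 * mueff / d)
    cs = (mueff + 2) / (d + mueff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((d + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (d + 1)) - 1) + cs
    chi_d = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d**2))

    pc = np.zeros(d)
    ps = np.zeros(d)
    C = np.eye(d)

    stall = 0
    for gen in range(max_generations):
        C = (C + C.T) / 2.0
        evals, B = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        sqrtC = B @ np.diag(np.sqrt(evals)) @ B.T
        inv_sqrtC = B @ np.diag(1.0 / np.sqrt(evals)) @ B.T

        z = rng.standard_normal((lam, d))
        y = z @ sqrtC.T
        xs = mean + sigma * y
        fs = np.empty(lam)
        for k in range(lam):
            fk, xk = fitness(xs[k])
            fs[k] = fk
            if fk < best_f:
                best_f, best_x = fk, xk
        order = np.argsort(fs)
        if not np.isfinite(fs[order[0]]):
            sigma *= 0.5  # whole population infeasible: contract and retry
            if sigma < 1e-14:
                break
            continue

        y_w = w @ y[order[:mu]]
        mean = mean + sigma * y_w
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (inv_sqrtC @ y_w)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_d
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w
        rank_mu = (y[order[:mu]].T * w) @ y[order[:mu]]
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_d - 1))
        sigma = min(sigma, 1e6)

        spread = fs[order[min(mu, lam - 1)]] - fs[order[0]]
        stall = stall + 1 if (np.isfinite(spread) and spread < ftol) else 0
        if stall >= 12 or sigma < 1e-12:
            break

    return best_f, best_x


def cmaes_start(
    target,
    init_guess,
    bounds,
    seed,
    sigma0: float | None = None,
    max_generations: int = 300,
    popsize: int | None = None,
    ftol: float = 1e-8,
    n_restarts: int = 2,
):
    """Maximise a log-density and return the best point found.

    Parameters
    ----------
    target : callable
        Log-density to maximise; may return -inf outside its support.
    init_guess : array
        Starting mean of the search distribution.
    bounds : sequence of (lower, upper)
        Box constraints per dimension; use +/-inf for unbounded sides.
    seed : int or numpy Generator
        Drives all sampling; identical seeds give identical results.
    sigma0 : float, optional
        Initial global step size; defaults to 15% of the median finite box
        width (or 0.5 if no side is finite).
    n_restarts : int
        Additional runs with doubled population after the first, each
        started from the incumbent best point; a run that fails to improve
        the incumbent by more than ``ftol`` ends the loop early.

    Returns
    -------
    ndarray
        The best point seen, guaranteed no worse than ``init_guess`` under
        ``target``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    init = np.asarray(init_guess, dtype=float).copy()
    d = init.size
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (d, 2):
        raise ValueError("bounds must provide one (lower, upper) pair per dimension")
    lower, upper = bounds[:, 0], bounds[:, 1]
    if np.any(lower >= upper):
        raise ValueError("each lower bound must be below its upper bound")

    def fitness(x):
        """Minimised objective: -target at the repaired point, plus penalty."""
        xr = _clip_to_box(x, lower, upper)
        val = target(xr)
        if not np.isfinite(val):
            return np.inf, xr
        return -val + 1e6 * float(np.sum((x - xr) ** 2)), xr

    mean = _clip_to_box(init, lower, upper)
    widths = upper - lower
    finite = np.isfinite(widths)
    if sigma0 is None:
        sigma0 = 0.15 * float(np.median(widths[finite])) if finite.any() else 0.5

    best_f, best_x = fitness(mean)
    if not np.isfinite(best_f):
        raise CMAESError(
            "objective is non-finite at the initial guess and its repair; "
            "check that the bounds intersect the support"
        )

    lam = popsize or 4 + int(3 * np.log(d))
    for run in range(1 + n_restarts):
        prev_f = best_f
        best_f, best_x = _run_once(
            fitness, best_x if run else mean, sigma0, lam * 2**run, rng,
            max_generations, ftol, best_f, best_x,
        )
        if run and prev_f - best_f <= ftol:
            break

    return best_x
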