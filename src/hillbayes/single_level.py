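"""Single-level (pooled) statistical model for dose-response data.

All K observations are treated as draws from one Hill curve with parameters
theta = (pIC50, Hill, sigma):

    y_j ~ TruncNormal( f(x_j; pIC50, Hill), sigma^2 ; [0, 100] ),

a Normal truncated to [0, 100] because % block data are capped to that range
at source.  Priors are independent uniforms, by default pIC50 ~ U(-1, 15),
Hill ~ U(0, 10), sigma ~ U(0, 50); the bounds are configurable for screens
with different dynamic ranges.  Everything is evaluated in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .core import hill_response
from .dataset import DoseResponseDataset

__all__ = [
    "SingleLevelParams",
    "UniformPriorBounds",
    "log_likelihood_point",
    "truncnorm_loglik",
    "log_prior_single",
    "log_posterior_single",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SingleLevelParams:
    """Parameter triple of the pooled model.

    pIC50 in log(Molar), Hill dimensionless, sigma (observation noise SD)
    in % block units.
    """

    pic50: float
    hill: float
    sigma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pic50, self.hill, self.sigma], dtype=float)


@dataclass(frozen=True)
class UniformPriorBounds:
    """Support box of the independent uniform priors."""

    pic50: tuple[float, float] = (-1.0, 15.0)
    hill: tuple[float, float] = (0.0, 10.0)
    sigma: tuple[float, float] = (0.0, 50.0)

    @property
    def log_density(self) -> float:
        """Log prior density at any in-support point (constant)."""
        return -sum(
            np.log(hi - lo) for lo, hi in (self.pic50, self.hill, self.sigma)
        )

    def contains(self, pic50: float, hill: float, sigma: float) -> bool:
        return (
            self.pic50[0] < pic50 < self.pic50[1]
            and self.hill[0] < hill < self.hill[1]
            and self.sigma[0] < sigma < self.sigma[1]
        )


def truncnorm_loglik(y, mean, sigma, lower: float = 0.0, upper: float = 100.0):
    """Log density of Normal(mean, sigma^2) truncated to [lower, upper].

    The normalising constant Phi((upper-mean)/sigma) - Phi((lower-mean)/sigma)
    depends on the point's own mean, so it is recomputed per point.  Because
    the Hill-curve mean always lies inside [0, 100], the interval retains at
    least the mass of a centred two-sigma window and a plain ndtr difference
    is numerically safe for any sigma down to 1e-3.

    Broadcasts over array arguments; returns -inf for y outside the interval.
    """
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    z = (y - mean) / sigma
    mass = ndtr((upper - mean) / sigma) - ndtr((lower - mean) / sigma)
    out = -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI - np.log(mass)
    out = np.where((y < lower) | (y > upper), -np.inf, out)
    return out if out.ndim else float(out)


def log_likelihood_point(y: float, x: float, params: SingleLevelParams) -> float:
    """Log likelihood of one observation under the truncated-normal model.

    ``y`` is % block in [0, 100], ``x`` the dose in uM.
    """
    if not 0.0 <= y <= 100.0:
        raise ValueError(f"response {y} outside [0, 100]; ingest must cap raw data")
    f = hill_response(x, params.pic50, params.hill)
    return truncnorm_loglik(y, f, params.sigma)


def log_prior_single(
    params: SingleLevelParams, bounds: UniformPriorBounds | None = None
) -> float:
    """Log density of the independent uniform priors; -inf outside the box."""
    bounds = bounds or UniformPriorBounds()
    if not bounds.contains(params.pic50, params.hill, params.sigma):
        return -np.inf
    return bounds.log_density


def log_posterior_single(
    data: DoseResponseDataset,
    params: SingleLevelParams,
    bounds: UniformPriorBounds | None = None,
) -> float:
    """Unnormalised log posterior: sum of point log likelihoods plus log prior."""
    lp = log_prior_single(params, bounds)
    if not np.isfinite(lp):
        return -np.inf
    f = hill_response(data.doses, params.pic50, params.hill)
    return float(np.sum(truncnorm_loglik(data.responses, f, params.sigma))) + lp
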