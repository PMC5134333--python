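"""Synthetic dose-response data with the structure the models assume.

Each simulated experiment draws its own (pIC50_i, Hill_i) — from a logistic
and a log-logistic population respectively, or holds one of them fixed —
evaluates the Hill curve at a shared dose grid, and adds observation noise.
By default the noise is drawn from the Normal truncated to [0, 100], i.e.
exactly the observation model the likelihood assumes; ``clip_noise=True``
instead draws unbounded Normal noise and caps the result into [0, 100],
emulating how raw screening data are capped at source.

Three presets reproduce the package's standard simulation studies:

===============  =====================================================
``fig9``         pIC50 ~ logistic(6, 0.1), Hill ~ log-logistic(1, 5),
                 sigma = 1; used for prior-to-posterior contraction and
                 noise-recovery studies (default 16 experiments).
``shamiodarone`` Hill fixed at 1, pIC50 ~ logistic(6, 0.2), sigma = 0.5,
                 5 experiments: variability lives in potency only.
``shamitriptyline`` pIC50 fixed at 6, Hill ~ log-logistic(1, 2.5),
                 sigma = 0.5, 5 experiments: variability in steepness only.
===============  =====================================================

Each preset measures 4 concentrations per experiment.  The default dose
grid is 4 log-equispaced points spanning IC50/30 to 30*IC50 of the
population-median potency, covering the informative region of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr, ndtri

from .core import hill_response, pic50_to_ic50
from .dataset import DoseResponseDataset

__all__ = ["GeneratorSpec", "generate_dataset", "preset", "default_doses", "PRESETS"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic compound/channel dataset.

    Give either (``mu``, ``s``) for a logistic pIC50 population or a fixed
    ``pic50``; either (``alpha``, ``beta``) for a log-logistic Hill
    population or a fixed ``hill``.  ``sigma`` is the observation-noise SD
    in % block.  ``concentrations=None`` selects the default grid.
    """

    mu: float | None = None
    s: float | None = None
    pic50: float | None = None
    alpha: float | None = None
    beta: float | None = None
    hill: float | None = None
    sigma: float = 1.0
    n_experiments: int = 5
    concentrations: tuple[float, ...] | None = None
    seed: int = 0
    clip_noise: bool = False
    compound: str = "synthetic"
    channel: str = "synthetic-channel"

    def __post_init__(self):
        fixed_p = self.pic50 is not None
        pop_p = self.mu is not None and self.s is not None
        if fixed_p == pop_p:
            raise ValueError("specify either a fixed pic50 or both (mu, s)")
        fixed_h = self.hill is not None
        pop_h = self.alpha is not None and self.beta is not None
        if fixed_h == pop_h:
            raise ValueError("specify either a fixed hill or both (alpha, beta)")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        if self.s is not None and self.s <= 0:
            raise ValueError("logistic scale s must be positive")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("log-logistic shape beta must be positive")
        if self.hill is not None and self.hill <= 0:
            raise ValueError("hill must be positive")
        if self.concentrations is not None:
            conc = tuple(float(c) for c in self.concentrations)
            if len(conc) == 0 or any(c <= 0 for c in conc):
                raise ValueError("concentrations must be a nonempty positive list")
            object.__setattr__(self, "concentrations", conc)

    @property
    def median_pic50(self) -> float:
        return self.pic50 if self.pic50 is not None else self.mu

    def doses(self) -> np.ndarray:
        if self.concentrations is not None:
            return np.asarray(self.concentrations, dtype=float)
        return default_doses(self.median_pic50)


def default_doses(pic50: float, n: int = 4, span: float = 30.0) -> np.ndarray:
    """Log-equispaced dose grid from IC50/span to span*IC50 (uM)."""
    ic50 = pic50_to_ic50(pic50)
    return np.geomspace(ic50 / span, ic50 * span, n)


def _truncnorm_noise(f, sigma, rng):
    """Draw y ~ Normal(f, sigma^2) truncated to [0, 100] by inversion."""
    a = ndtr(-f / sigma)
    b = ndtr((100.0 - f) / sigma)
    u = rng.uniform(a, b)
    return f + sigma * ndtri(u)


def generate_dataset(spec: GeneratorSpec) -> DoseResponseDataset:
    """Simulate the dataset described by ``spec``; reproducible via its seed."""
    rng = np.random.default_rng(spec.seed)
    doses = spec.doses()
    n_per = doses.size

    if spec.pic50 is not None:
        pic50_i = np.full(spec.n_experiments, float(spec.pic50))
    else:
        pic50_i = rng.logistic(spec.mu, spec.s, size=spec.n_experiments)
    if spec.hill is not None:
        hill_i = np.full(spec.n_experiments, float(spec.hill))
    else:
        u = rng.uniform(size=spec.n_experiments)
        hill_i = spec.alpha * (u / (1.0 - u)) ** (1.0 / spec.beta)

    all_doses, all_resp, all_ids = [], [], []
    for i in range(spec.n_experiments):
        f = hill_response(doses, pic50_i[i], hill_i[i])
        if spec.sigma == 0:
            y = f
        elif spec.clip_noise:
            y = np.clip(f + rng.normal(0.0, spec.sigma, size=n_per), 0.0, 100.0)
        else:
            y = _truncnorm_noise(f, spec.sigma, rng)
        all_doses.append(doses)
        all_resp.append(y)
        all_ids.append(np.full(n_per, i + 1, dtype=int))

    return DoseResponseDataset(
        np.concatenate(all_doses),
        np.concatenate(all_resp),
        np.concatenate(all_ids),
        compound=spec.compound,
        channel=spec.channel,
    )


PRESETS: dict[str, GeneratorSpec] = {
    "fig9": GeneratorSpec(
        mu=6.0, s=0.1, alpha=1.0, beta=5.0, sigma=1.0,
        n_experiments=16, compound="fig9-study", channel="synthetic-channel",
    ),
    "shamiodarone": GeneratorSpec(
        hill=1.0, mu=6.0, s=0.2, sigma=0.5,
        n_experiments=5, compound="shamiodarone", channel="synthetic-channel",
    ),
    "shamitriptyline": GeneratorSpec(
        pic50=6.0, alpha=1.0, beta=2.5, sigma=0.5,
        n_experiments=5, compound="shamitriptyline", channel="synthetic-channel",
    ),
}


def preset(name: str, **overrides) -> GeneratorSpec:
    """Return the named study spec, optionally overriding fields.

    >>> preset("shamiodarone", seed=7).sigma
    0.5
    """
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(base, **overrides) if overrides else base
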