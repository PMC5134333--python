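"""Deterministic Hill dose-response model and the pIC50/IC50 reparameterisation.

The response of an ion channel to a blocking compound at concentration ``x``
(in micromolar) is modelled with the two-parameter Hill curve

    f(x; IC50, Hill) = 100 / (1 + (IC50 / x)**Hill)        [% block]

with bottom fixed at 0% and top at 100%.  Internally all potency arithmetic
uses the log-molar transform

    pIC50 = 6 - log10(IC50 [uM]),

because linear changes in pIC50 produce roughly linear changes in the curve
on the usual log-concentration axis, which is what sampling and optimisation
algorithms need.  IC50 in micromolar appears only at input/output boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["hill_response", "ic50_to_pic50", "pic50_to_ic50"]

_LN10 = np.log(10.0)


def ic50_to_pic50(ic50):
    """Convert IC50 in micromolar to pIC50 in log(Molar) units.

    pIC50 = 6 - log10(IC50[uM]); an IC50 of 1 uM maps to pIC50 = 6.
    """
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("IC50 must be strictly positive (micromolar).")
    out = 6.0 - np.log10(ic50)
    return out if out.ndim else float(out)


def pic50_to_ic50(pic50):
    """Inverse of :func:`ic50_to_pic50`: IC50[uM] = 10**(6 - pIC50)."""
    pic50 = np.asarray(pic50, dtype=float)
    out = np.power(10.0, 6.0 - pic50)
    return out if out.ndim else float(out)


def hill_response(x, pic50, hill):
    """Percent channel block at concentration ``x`` uM.

    Evaluates 100 / (1 + (IC50/x)**Hill) with IC50 = 10**(6 - pIC50),
    computed stably in log-concentration space as a scaled logistic:

        f = 100 * expit( Hill * ln(10) * (log10 x - (6 - pIC50)) ).

    ``x = 0`` returns exactly 0, the analytic limit (zero-dose controls are
    legitimate data).  Broadcasts over any mix of array arguments.

    Raises
    ------
    ValueError
        If any ``x`` is negative or any ``hill`` is not strictly positive.
    """
    x = np.asarray(x, dtype=float)
    pic50 = np.asarray(pic50, dtype=float)
    hill = np.asarray(hill, dtype=float)
    if np.any(x < 0):
        raise ValueError("Concentrations must be non-negative (micromolar).")
    if np.any(hill <= 0):
        raise ValueError("The Hill coefficient must be strictly positive.")
    with np.errstate(divide="ignore"):
        logx = np.log10(x)  # -inf at x=0 -> expit(-inf) = 0, the limit
    out = 100.0 * expit(hill * _LN10 * (logx - (6.0 - pic50)))
    return out if out.ndim else float(out)
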