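"""Arrhenius analysis and rate-ratio thermodynamics.

The activation energy of a conformational step follows from an ordinary
least-squares fit of ln k against 1/T (kelvin):

    ln k = ln A − Ea / (R·T),    Ea = −slope · R,

with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹.  Differences in activation energy
between constructs, fold changes between rate constants, and barrier-height
differences via transition-state theory,

    ΔΔG‡ = R·T·ln(k2/k1),

are all simple arithmetic on fitted or tabulated rates; they are collected
here so reports use one set of constants and conventions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .datatypes import ArrheniusFit, FoldChange, R_KCAL, RateSeries, celsius_to_kelvin
from .errors import DomainError

__all__ = [
    "arrhenius_fit",
    "ea_difference",
    "fold_change",
    "ddg_from_rates",
    "strap_fraction_of_ea",
]


def arrhenius_fit(rates: RateSeries) -> ArrheniusFit:
    """Fit ln k versus 1/T_K by unweighted ordinary least squares.

    Requires at least two distinct temperatures and positive rates
    (enforced by :class:`RateSeries`).  Returns the activation energy in
    kcal/mol, ln of the pre-exponential factor, the slope in kelvin and r².
    """
    if len(rates.T_C) < 2:
        raise DomainError("need at least 2 (T, k) points")
    t_k = celsius_to_kelvin(rates.T_C)
    x = 1.0 / t_k
    if np.ptp(x) == 0:
        raise DomainError("all temperatures identical; Arrhenius slope is rank-deficient")
    y = np.log(rates.k)
    res = stats.linregress(x, y)
    return ArrheniusFit(
        Ea=float(-res.slope * R_KCAL),
        lnA=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=len(rates.T_C),
    )


def ea_difference(a: ArrheniusFit, b: ArrheniusFit) -> float:
    """Signed activation-energy difference a.Ea − b.Ea (kcal/mol)."""
    return a.Ea - b.Ea


def strap_fraction_of_ea(wt: ArrheniusFit, deletion: ArrheniusFit) -> dict[str, float]:
    """Two readings of "what fraction of the barrier the strap contributes".

    ``difference_over_wt`` is (Ea_wt − Ea_del)/Ea_wt; ``residual_over_wt``
    is Ea_del/Ea_wt.  Both are returned because prose summaries of such
    numbers are ambiguous between the two.
    """
    return {
        "difference_over_wt": (wt.Ea - deletion.Ea) / wt.Ea,
        "residual_over_wt": deletion.Ea / wt.Ea,
    }


def fold_change(k_num: float, k_den: float) -> FoldChange:
    """Rate ratio k_num/k_den with an integer presentation value.

    The presented value rounds half up ("sevenfold" for 7.2, "24-fold" for
    24.3).
    """
    if k_den <= 0:
        raise DomainError("denominator rate must be > 0")
    raw = k_num / k_den
    return FoldChange(raw=raw, presented=int(math.floor(raw + 0.5)))


def ddg_from_rates(k1: float, k2: float, t_c: float) -> float:
    """Barrier-height difference ΔΔG‡ = R·T_K·ln(k2/k1) in kcal/mol.

    Positive when k2 > k1 (the second process is faster, i.e. its barrier
    is lower by the returned amount).  ``t_c`` defaults to nothing — pass
    the experiment temperature of the rate pair.
    """
    if k1 <= 0 or k2 <= 0:
        raise DomainError("rates must be > 0")
    return float(R_KCAL * celsius_to_kelvin(t_c) * np.log(k2 / k1))
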