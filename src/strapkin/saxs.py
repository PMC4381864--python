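"""Two-state decomposition of SAXS pair-distance distributions.

A measured P(r) is modelled as a non-negative linear combination of an
extended "open" reference and a compact "closed" reference:

    P_obs(r) ≈ c_open · P_open(r) + c_closed · P_closed(r)

The reported closed-state fraction is c_closed / (c_open + c_closed), and
fit quality is an R factor in the crystallographic sense,

    R = Σ_r |P_obs(r) − P_calc(r)| / Σ_r |P_obs(r)|,

evaluated over the fit region.  Both references are area-normalised before
fitting so the coefficient ratio is directly interpretable as a population
fraction; the raw coefficients are also reported.

The fit region is restricted to grid points where both the observed curve
and the closed reference are effectively non-zero (above a small fraction
of their own maxima).  References are linearly interpolated onto the
observed grid; observed data are never resampled.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

from .datatypes import PrCurve, TwoStateFit
from .errors import (
    DegenerateFitError,
    FitDomainError,
    GridMismatchError,
    NormalizationError,
    UndefinedStatisticError,
)
from .io import read_gnom_out, read_pr_table  # re-exported: the module's readers

__all__ = [
    "read_gnom_out",
    "read_pr_table",
    "normalize_pr",
    "fit_two_state",
    "r_merge",
]

#: Fraction of a curve's own maximum below which a point is treated as zero
#: when delimiting the fit region.
NONZERO_FRACTION = 1e-4


def normalize_pr(curve: PrCurve) -> PrCurve:
    """Scale P(r) so its trapezoid integral (of |p|) equals 1.

    Idempotent; the r grid is unchanged.  Per-point errors, if present, are
    scaled by the same factor.
    """
    if len(curve.r) < 2:
        raise NormalizationError("need at least 2 grid points to integrate")
    area = np.trapezoid(np.abs(curve.p), curve.r)
    if area <= 0:
        raise NormalizationError("curve has zero area; cannot normalise")
    err = curve.err / area if curve.err is not None else None
    return curve.with_p(curve.p / area, err=err)


def r_merge(obs: PrCurve, calc: PrCurve, pointwise: bool = False) -> float:
    """R factor between observed and calculated P(r) on a common grid.

    Default is the ratio of summed absolute deviations to summed absolute
    observations (scale-invariant; 0 iff the curves are identical).  The
    strictly pointwise mean of |ΔP|/|P_obs| is available via
    ``pointwise=True`` for comparison but diverges wherever P_obs ≈ 0.
    """
    if not np.array_equal(obs.r, calc.r):
        raise GridMismatchError("observed and calculated curves are on different grids")
    denom_total = np.sum(np.abs(obs.p))
    if denom_total == 0:
        raise UndefinedStatisticError("Σ|P_obs| is zero; R undefined")
    dev = np.abs(obs.p - calc.p)
    if pointwise:
        mask = np.abs(obs.p) > 0
        return float(np.mean(dev[mask] / np.abs(obs.p[mask])))
    return float(np.sum(dev) / denom_total)


def _fit_region(obs_p: np.ndarray, closed_p: np.ndarray, threshold: float) -> np.ndarray:
    mask = (np.abs(obs_p) > threshold * np.max(np.abs(obs_p))) & (
        np.abs(closed_p) > threshold * np.max(np.abs(closed_p))
    )
    return mask


def fit_two_state(
    obs: PrCurve,
    open_ref: PrCurve,
    closed_ref: PrCurve,
    nonzero_fraction: float = NONZERO_FRACTION,
    normalize: bool = True,
) -> TwoStateFit:
    """Least-squares open/closed decomposition of an observed P(r).

    Solves for non-negative coefficients (c_open, c_closed) minimising the
    squared residual over the fit region, reports
    fraction_closed = c_closed/(c_open + c_closed) and the R factor of the
    fitted model on that region.

    Parameters
    ----------
    nonzero_fraction:
        Threshold (fraction of each curve's own maximum) defining the
        region where both the observed data and the closed reference are
        considered non-zero.
    normalize:
        Area-normalise all three curves before fitting (default).  With
        ``False`` the raw coefficients act on the curves as given; the
        fraction is still their ratio.
    """
    if normalize:
        obs = normalize_pr(obs)
        open_ref = normalize_pr(open_ref)
        closed_ref = normalize_pr(closed_ref)

    open_i = np.interp(obs.r, open_ref.r, open_ref.p, left=0.0, right=0.0)
    closed_i = np.interp(obs.r, closed_ref.r, closed_ref.p, left=0.0, right=0.0)

    mask = _fit_region(obs.p, closed_i, nonzero_fraction)
    if not np.any(mask):
        raise FitDomainError("no overlapping non-zero region between data and closed reference")

    A = np.column_stack([open_i[mask], closed_i[mask]])
    coeffs, _ = nnls(A, obs.p[mask])
    c_open, c_closed = float(coeffs[0]), float(coeffs[1])
    total = c_open + c_closed
    if total == 0:
        raise DegenerateFitError("both mixture coefficients are zero")
    fraction = c_closed / total

    model = c_open * open_i + c_closed * closed_i
    obs_region = PrCurve(r=obs.r[mask], p=obs.p[mask])
    calc_region = PrCurve(r=obs.r[mask], p=model[mask])
    return TwoStateFit(
        fraction_closed=fraction,
        r_merge=r_merge(obs_region, calc_region),
        coeff_open=c_open,
        coeff_closed=c_closed,
        n_points_used=int(np.sum(mask)),
    )
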