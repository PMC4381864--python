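"""Exponential kinetics of conformational-change time courses.

Covers the observables used to time chaperone closure and reopening:

* ratio of donor/acceptor FRET channels, oriented so the kinetic change is
  positive-going;
* single-exponential rise (``m1 + m2·(1 − e^{−m3 t})``) and decay
  (``m1 + m2·e^{−m3 t}``) fits, where ``m1`` is the time-zero value,
  ``m2`` the amplitude and ``m3`` the rate constant in min⁻¹;
* area normalisation of steady-state scans;
* percent-change normalisation of EPR peak heights;
* a constrained joint fit of the mobile and immobile EPR peak series under
  one shared rate constant.

Least squares is unweighted (homoscedastic errors in y).  Initialisation is
parameter-free: offset from the first observation, amplitude from
last − first, rate from ln 2 over the first time the signal crosses half
its total change.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import least_squares

from .datatypes import ExpFit, JointEprFit, TimeSeries
from .errors import (
    DomainError,
    GridMismatchError,
    InvalidSpecError,
    NonIdentifiableError,
    NormalizationError,
)

__all__ = [
    "fret_ratio",
    "fit_exponential",
    "fit_epr_joint",
    "normalize_scan",
    "peak_percent_change",
]

_XTOL = 1e-8
_MAX_NFEV = 10_000


def fret_ratio(
    donor: TimeSeries,
    acceptor: TimeSeries,
    orientation: str = "donor/acceptor",
    normalize: bool = False,
) -> TimeSeries:
    """Pointwise ratio of the two FRET channels.

    ``orientation`` selects ``"donor/acceptor"`` or ``"acceptor/donor"`` so
    the change of interest can be graphed positive-going.  With
    ``normalize=True`` the ratio is divided by its initial value.
    """
    if orientation not in ("donor/acceptor", "acceptor/donor"):
        raise InvalidSpecError(f"unknown orientation {orientation!r}")
    if not np.array_equal(donor.t, acceptor.t):
        raise GridMismatchError("donor and acceptor are on different time grids")
    num, den = (donor, acceptor) if orientation == "donor/acceptor" else (acceptor, donor)
    zeros = np.flatnonzero(den.y == 0)
    if len(zeros):
        raise DomainError(f"zero denominator at t = {den.t[zeros[0]]:g} min")
    y = num.y / den.y
    if normalize:
        y = y / y[0]
    return TimeSeries(t=donor.t, y=y, channel="ratio")


def _half_change_rate(t: np.ndarray, y: np.ndarray) -> float:
    """ln 2 over the first time |y − y0| crosses half the total change."""
    total = abs(y[-1] - y[0])
    crossed = np.flatnonzero(np.abs(y - y[0]) >= total / 2.0)
    t_half = t[crossed[0]] if len(crossed) and t[crossed[0]] > 0 else (t[-1] - t[0]) / 2.0
    return np.log(2.0) / t_half


def _noise_floor(y: np.ndarray) -> float:
    """Robust noise estimate from second differences (trend-insensitive)."""
    if len(y) < 3:
        return 0.0
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    return 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)


def fit_exponential(ts: TimeSeries, direction: str) -> ExpFit:
    """Fit a single-exponential rise or decay to a time series.

    Raises :class:`NonIdentifiableError` when the series shows no signal
    change above the noise floor.  Non-convergence is reported through the
    ``converged`` flag, never silently accepted.
    """
    if direction not in ("rise", "decay"):
        raise InvalidSpecError(f"direction must be 'rise' or 'decay', got {direction!r}")
    if len(ts) < 3:
        raise InvalidSpecError("need at least 3 points to fit")
    if len(ts) < 4:
        warnings.warn("fewer than 4 points; exponential fit is minimally determined",
                      stacklevel=2)
    t, y = ts.t, ts.y
    total_change = abs(y[-1] - y[0])
    if total_change == 0 or total_change < 3.0 * _noise_floor(y):
        raise NonIdentifiableError("no signal change detectable above the noise floor")

    k0 = _half_change_rate(t, y)
    if t[-1] - t[0] < np.log(2.0) / k0:  # soft span check: < 1 half-life sampled
        warnings.warn("time span covers less than one apparent half-life", stacklevel=2)

    if direction == "rise":
        x0 = np.array([y[0], y[-1] - y[0], k0])

        def resid(p):
            return p[0] + p[1] * (1.0 - np.exp(-p[2] * t)) - y
    else:
        x0 = np.array([y[-1], y[0] - y[-1], k0])

        def resid(p):
            return p[0] + p[1] * np.exp(-p[2] * t) - y

    sol = least_squares(
        resid, x0,
        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=_XTOL, ftol=1e-15, gtol=1e-15, max_nfev=_MAX_NFEV,
    )
    m1, m2, m3 = sol.x
    # m1 is the model's literal first parameter: the t=0 value for a rise,
    # the asymptote for a decay (t=0 value is then m1 + m2)
    return ExpFit(
        m1=float(m1), m2=float(m2), m3=float(m3),
        direction=direction,
        rss=float(2.0 * sol.cost),
        converged=bool(sol.success),
    )


def fit_epr_joint(
    mobile: TimeSeries,
    immobile: TimeSeries,
    fit_offsets: bool = False,
) -> JointEprFit:
    """Joint exponential fit of both EPR peak series with one shared rate.

    Each channel is modelled as ``amp·(1 − e^{−k t})`` (offsets fixed at 0,
    appropriate for percent-change data; ``fit_offsets=True`` floats a
    per-channel offset).  The summed squared residual of both channels is
    minimised over (k, amp_mobile, amp_immobile).
    """
    for name, ts in (("mobile", mobile), ("immobile", immobile)):
        if len(ts) < 4:
            raise InvalidSpecError(f"{name} series needs at least 4 points")
    ref = mobile if abs(mobile.y[-1] - mobile.y[0]) >= abs(immobile.y[-1] - immobile.y[0]) \
        else immobile
    if abs(ref.y[-1] - ref.y[0]) == 0:
        raise NonIdentifiableError("no signal change in either channel")
    k0 = _half_change_rate(ref.t, ref.y)
    amps0 = [mobile.y[-1] - mobile.y[0], immobile.y[-1] - immobile.y[0]]

    if fit_offsets:
        x0 = np.array([k0, *amps0, mobile.y[0], immobile.y[0]])
    else:
        x0 = np.array([k0, *amps0])

    def resid(p):
        k, am, ai = p[0], p[1], p[2]
        om, oi = (p[3], p[4]) if fit_offsets else (0.0, 0.0)
        rm = om + am * (1.0 - np.exp(-k * mobile.t)) - mobile.y
        ri = oi + ai * (1.0 - np.exp(-k * immobile.t)) - immobile.y
        return np.concatenate([rm, ri])

    lo = np.full_like(x0, -np.inf)
    hi = np.full_like(x0, np.inf)
    lo[0] = 1e-12
    sol = least_squares(resid, x0, bounds=(lo, hi),
                        xtol=_XTOL, ftol=1e-15, gtol=1e-15, max_nfev=_MAX_NFEV)
    return JointEprFit(
        k_shared=float(sol.x[0]),
        amp_mobile=float(sol.x[1]),
        amp_immobile=float(sol.x[2]),
        rss_joint=float(2.0 * sol.cost),
        converged=bool(sol.success),
    )


def normalize_scan(scan: TimeSeries) -> TimeSeries:
    """Scale a steady-state scan so the area under the curve is 1.

    Works on any (x, y) series (x is typically wavelength); idempotent.
    """
    if len(scan) < 2:
        raise NormalizationError("need at least 2 points to integrate")
    area = np.trapezoid(scan.y, scan.t)
    if area == 0:
        raise NormalizationError("scan has zero area; cannot normalise")
    return TimeSeries(t=scan.t, y=scan.y / area, channel=scan.channel)


def peak_percent_change(raw: TimeSeries) -> TimeSeries:
    """Convert raw peak heights to percent change over the time course.

    ``PC(t) = 100·(y(t) − y(t0)) / |y(t_end) − y(t0)|`` — traces start at 0
    and end at +100 or −100 depending on the direction of change.  Uses the
    realised endpoints, not a fitted asymptote.
    """
    if len(raw) < 2:
        raise InvalidSpecError("need at least 2 points")
    span = raw.y[-1] - raw.y[0]
    if span == 0:
        raise NormalizationError("start and end values are equal; percent change undefined")
    y = 100.0 * (raw.y - raw.y[0]) / abs(span)
    return TimeSeries(t=raw.t, y=y, channel=raw.channel)
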