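"""Core value types shared across the analysis stages.

All containers are frozen-ish dataclasses holding numpy arrays; validation
happens at construction so downstream code can assume well-formed inputs.
Units are fixed package-wide: distances in Å, time in minutes, rates in
min⁻¹, temperatures in °C at the interface (converted to kelvin internally),
energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, InvalidSpecError

#: Gas constant in kcal mol⁻¹ K⁻¹.
R_KCAL = 1.9872e-3

#: Conversion from °C to K.
KELVIN_OFFSET = 273.15


def celsius_to_kelvin(t_c: float | np.ndarray) -> float | np.ndarray:
    t_k = np.asarray(t_c, dtype=float) + KELVIN_OFFSET
    if np.any(t_k <= 0):
        raise DomainError("temperature at or below absolute zero")
    return t_k if t_k.ndim else float(t_k)


@dataclass
class PrCurve:
    """A pair-distance distribution P(r) on an r grid.

    ``p`` has units of probability density per Å; after normalisation the
    trapezoid integral over ``r`` is 1.  ``err`` is an optional per-point
    standard deviation on the same grid.
    """

    r: np.ndarray
    p: np.ndarray
    err: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.p.shape:
            raise InvalidSpecError("r and p must be 1-D arrays of equal length")
        if len(self.r) >= 2 and np.any(np.diff(self.r) <= 0):
            raise InvalidSpecError("r grid must be strictly increasing")
        if len(self.r) and self.r[0] < 0:
            raise InvalidSpecError("r grid must be non-negative")
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if self.err.shape != self.p.shape:
                raise InvalidSpecError("err must match the grid length")

    @property
    def dmax(self) -> float:
        """Largest r at which P(r) is effectively non-zero."""
        nz = np.flatnonzero(np.abs(self.p) > 1e-12 * max(np.max(np.abs(self.p)), 1e-300))
        return float(self.r[nz[-1]]) if len(nz) else 0.0

    def with_p(self, p: np.ndarray, err: np.ndarray | None = None) -> "PrCurve":
        return replace(self, p=np.asarray(p, dtype=float), err=err)


@dataclass
class TwoStateFit:
    """Result of the open/closed linear decomposition of a P(r) curve."""

    fraction_closed: float
    r_merge: float
    coeff_open: float
    coeff_closed: float
    n_points_used: int

    @property
    def percent_closed(self) -> float:
        return 100.0 * self.fraction_closed


@dataclass
class TimeSeries:
    """A sampled signal versus time (minutes)."""

    t: np.ndarray
    y: np.ndarray
    channel: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise InvalidSpecError("t and y must be 1-D arrays of equal length")
        if len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise InvalidSpecError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ExpFit:
    """Single-exponential fit parameters.

    ``m1`` is the time-zero value of the underlying asymptote description,
    ``m2`` the amplitude and ``m3`` the rate constant in min⁻¹.  For a rise
    the model is ``m1 + m2·(1 − e^{−m3·t})``; for a decay
    ``m1 + m2·e^{−m3·t}``.
    """

    m1: float
    m2: float
    m3: float
    direction: str
    rss: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.direction == "rise":
            return self.m1 + self.m2 * (1.0 - np.exp(-self.m3 * t))
        return self.m1 + self.m2 * np.exp(-self.m3 * t)


@dataclass
class JointEprFit:
    """Shared-rate joint fit of the mobile and immobile EPR peak series."""

    k_shared: float
    amp_mobile: float
    amp_immobile: float
    rss_joint: float
    converged: bool


@dataclass
class RateSeries:
    """Rate constants measured at a set of temperatures."""

    T_C: np.ndarray
    k: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.T_C = np.asarray(self.T_C, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.T_C.shape != self.k.shape or self.T_C.ndim != 1:
            raise InvalidSpecError("T_C and k must be 1-D arrays of equal length")
        if np.any(self.k <= 0):
            raise DomainError("all rates must be positive")
        if np.any(self.T_C <= -KELVIN_OFFSET):
            raise DomainError("temperatures must be above absolute zero")


@dataclass
class ArrheniusFit:
    """ln k = ln A − Ea/(R·T) regression result.

    ``slope`` is in kelvin (equal to −Ea/R); Ea in kcal/mol.
    """

    Ea: float
    lnA: float
    slope: float
    r_squared: float
    n: int

    def k_at(self, t_c: float) -> float:
        """Rate predicted by the fitted line at temperature ``t_c`` (°C)."""
        return float(np.exp(self.lnA + self.slope / celsius_to_kelvin(t_c)))


@dataclass
class CycleParams:
    """Rate constants and gating flags of the open ⇌ closed ATPase cycle.

    Hydrolysis only proceeds with ATP bound *and* Mg²⁺ present; AMPPNP (a
    non-hydrolysable analog) always gates hydrolysis off.  ``k_close`` may
    alternatively be given through an Arrhenius pair (``lnA``, ``Ea``) plus
    the temperature ``T_C``.
    """

    k_close: float | None = None
    k_reopen: float = 0.0
    k_hyd: float = 0.0
    mg_present: bool = True
    nucleotide: str = "ATP"
    T_C: float = 30.0
    lnA: float | None = None
    Ea: float | None = None
    atp_per_cycle: float = 1.0

    def __post_init__(self):
        if self.nucleotide not in ("ATP", "AMPPNP", "ADP", "none"):
            raise InvalidSpecError(f"unknown nucleotide {self.nucleotide!r}")
        if self.k_close is None:
            if self.lnA is None or self.Ea is None:
                raise InvalidSpecError("provide k_close or an (lnA, Ea) pair")
        for name in ("k_reopen", "k_hyd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if self.k_close is not None and self.k_close < 0:
            raise InvalidSpecError("k_close must be >= 0")

    @property
    def k_close_effective(self) -> float:
        if self.k_close is not None:
            return self.k_close
        return float(np.exp(self.lnA - self.Ea / (R_KCAL * celsius_to_kelvin(self.T_C))))

    @property
    def k_hyd_effective(self) -> float:
        """Hydrolysis rate after applying the Mg²⁺ / nucleotide gate."""
        if self.nucleotide != "ATP" or not self.mg_present:
            return 0.0
        return self.k_hyd


@dataclass
class Trajectory:
    """State-occupancy time course of the cycle model.

    ``atp_turnover`` counts cumulative hydrolysis events per dimer
    (non-decreasing; zero whenever the hydrolysis gate is closed).
    """

    t: np.ndarray
    f_open: np.ndarray
    f_closed: np.ndarray
    atp_turnover: np.ndarray
    label: str = ""

    def __post_init__(self):
        for name in ("t", "f_open", "f_closed", "atp_turnover"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, a)) != n for a in ("f_open", "f_closed", "atp_turnover")):
            raise InvalidSpecError("trajectory arrays must share one length")


@dataclass
class FoldChange:
    """A rate ratio plus its integer presentation value (round half up)."""

    raw: float
    presented: int

    def __float__(self) -> float:
        return self.raw
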