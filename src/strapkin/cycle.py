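"""Mg²⁺-gated kinetic cycle of the open ⇌ closed conformational change.

The model lumps every open-like species (apo, ATP-bound pre-closure,
post-hydrolysis ADP state) into "open" and treats the N-domain-dimerised
state as "closed":

    open  --k_close-->  closed
    closed --k_reopen--> open
    closed --k_hyd-->    open   (ATP hydrolysis; only with ATP + Mg²⁺)

With the hydrolysis gate closed (AMPPNP, or ATP without Mg²⁺) the system
is a two-state linear relaxation with closed-form occupancies

    f_closed(t) = k_c/(k_c+k_r) · (1 − e^{−(k_c+k_r)t}).

Opening the gate (adding Mg²⁺) adds the hydrolysis channel, and the
population relaxes toward the cycling steady state
f_closed* = k_c/(k_c + k_hyd + k_r) with rate k_c + k_hyd + k_r.  Because
hydrolysis is much faster than closure, closure is the rate-limiting step
of the cycle and the steady state is predominantly open.

A stochastic (Gillespie) engine over a finite number of dimers is provided
as an independent check of the deterministic solutions and for studies of
finite-sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CycleParams, R_KCAL, Trajectory, celsius_to_kelvin
from .errors import DomainError, InvalidSpecError

__all__ = [
    "simulate_closure",
    "simulate_mg_jump",
    "simulate_stochastic",
    "effective_turnover",
    "closure_rate_at_T",
    "hysteresis_check",
    "HysteresisResult",
]


def _propagate(f0: float, k_c: float, k_out: float, k_h: float, dt: np.ndarray):
    """Closed-form two-state evolution over elapsed times ``dt``.

    ``k_out`` is the total closed→open rate (k_reopen + k_hyd).  Returns
    (f_closed(dt), hydrolysis events per dimer accumulated over dt).
    """
    lam = k_c + k_out
    if lam == 0:
        return np.full_like(dt, f0, dtype=float), np.zeros_like(dt, dtype=float)
    f_inf = k_c / lam
    decay = np.exp(-lam * dt)
    f = f_inf + (f0 - f_inf) * decay
    # turnover = k_h * integral of f_closed dt (events per dimer)
    integral = f_inf * dt + (f0 - f_inf) * (1.0 - decay) / lam
    return f, k_h * integral


def simulate_closure(params: CycleParams, t_grid: np.ndarray) -> Trajectory:
    """Closure under a non-hydrolysing condition (AMPPNP, or ATP − Mg²⁺).

    Starts fully open.  Requires the hydrolysis gate to be off; use
    :func:`simulate_mg_jump` for hydrolysing scenarios.
    """
    if params.k_hyd_effective > 0:
        raise InvalidSpecError(
            "simulate_closure requires the hydrolysis gate off (AMPPNP or no Mg2+)"
        )
    t = np.asarray(t_grid, dtype=float)
    f_closed, _ = _propagate(0.0, params.k_close_effective, params.k_reopen, 0.0, t - t[0])
    return Trajectory(
        t=t, f_open=1.0 - f_closed, f_closed=f_closed,
        atp_turnover=np.zeros_like(t), label="closure",
    )


def simulate_mg_jump(params: CycleParams, t_mg: float, t_grid: np.ndarray) -> Trajectory:
    """Closure with ATP but no Mg²⁺, then Mg²⁺ addition at ``t_mg``.

    Before ``t_mg`` the closed state accumulates without hydrolysis; after,
    the hydrolysis channel opens (closed → open at k_hyd + k_reopen) and
    the population relaxes toward the cycling steady state
    f_closed* = k_c/(k_c + k_hyd + k_r).  ATP turnover accumulates only
    after the jump.
    """
    if params.nucleotide != "ATP":
        raise InvalidSpecError("the Mg2+-jump experiment requires ATP")
    t = np.asarray(t_grid, dtype=float)
    if not (t[0] <= t_mg <= t[-1]):
        raise InvalidSpecError("t_mg must lie inside the time grid")
    k_c = params.k_close_effective
    k_r, k_h = params.k_reopen, params.k_hyd

    f_closed = np.empty_like(t)
    turnover = np.empty_like(t)
    pre = t <= t_mg
    f_closed[pre], _ = _propagate(0.0, k_c, k_r, 0.0, t[pre] - t[0])
    turnover[pre] = 0.0

    f_at_jump, _ = _propagate(0.0, k_c, k_r, 0.0, np.asarray([t_mg - t[0]]))
    post = ~pre
    f_closed[post], tv = _propagate(float(f_at_jump[0]), k_c, k_r + k_h, k_h, t[post] - t_mg)
    turnover[post] = params.atp_per_cycle * tv
    return Trajectory(
        t=t, f_open=1.0 - f_closed, f_closed=f_closed,
        atp_turnover=turnover, label="mg_jump",
    )


def simulate_stochastic(
    params: CycleParams,
    t_grid: np.ndarray,
    n_molecules: int = 10_000,
    seed: int | None = None,
    t_mg: float | None = None,
) -> Trajectory:
    """Finite-population simulation of the same scheme.

    Occupancies are sampled exactly at the grid times: over each interval
    every molecule transitions according to the analytic two-state
    propagator (binomial draws), which is the exact Markov-chain skeleton.
    Cumulative hydrolysis events are drawn Poisson with mean
    k_hyd·∫n_closed dt estimated from the realised occupancy.

    ``t_mg`` switches the hydrolysis gate on at that time (requires ATP);
    with ``t_mg=None`` the gate state follows ``params`` throughout.
    """
    if seed is None:
        raise InvalidSpecError("the stochastic engine requires an explicit seed")
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, dtype=float)
    k_c, k_r = params.k_close_effective, params.k_reopen

    n_closed = 0
    events = 0.0
    f_closed = np.zeros_like(t)
    turnover = np.zeros_like(t)
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        if t_mg is None:
            k_h = params.k_hyd_effective
        else:
            k_h = params.k_hyd if t[i - 1] >= t_mg else 0.0
        lam = k_c + k_r + k_h
        if lam > 0:
            f_inf = k_c / lam
            stay = np.exp(-lam * dt)
            p_oc = f_inf * (1.0 - stay)          # open -> closed over dt
            p_co = (1.0 - f_inf) * (1.0 - stay)  # closed -> open over dt
            n_open = n_molecules - n_closed
            prev_closed = n_closed
            n_closed = int(rng.binomial(n_open, p_oc) + rng.binomial(prev_closed, 1 - p_co))
            if k_h > 0:
                mean_events = k_h * 0.5 * (prev_closed + n_closed) * dt
                events += rng.poisson(mean_events)
        f_closed[i] = n_closed / n_molecules
        turnover[i] = params.atp_per_cycle * events / n_molecules
    return Trajectory(
        t=t, f_open=1.0 - f_closed, f_closed=f_closed,
        atp_turnover=turnover, label="stochastic",
    )


def effective_turnover(k_close: float, k_hyd: float) -> float:
    """Cycle-completion rate of two sequential irreversible steps.

    1/(1/k_close + 1/k_hyd); always below the slower of the two, which is
    why a slow closure step caps the observable ATPase rate.
    """
    if k_close <= 0 or k_hyd <= 0:
        raise DomainError("both rates must be > 0")
    return 1.0 / (1.0 / k_close + 1.0 / k_hyd)


def closure_rate_at_T(lnA: float, Ea: float, t_c: float) -> float:
    """Arrhenius-parameterised closure rate exp(lnA − Ea/(R·T_K)) in min⁻¹."""
    return float(np.exp(lnA - Ea / (R_KCAL * celsius_to_kelvin(t_c))))


@dataclass
class HysteresisResult:
    trajectory: Trajectory
    f_closed_end_hot: float
    f_closed_end_cold: float


def hysteresis_check(
    params_hot: CycleParams,
    params_cold: CycleParams,
    t_hot: float,
    t_cold: float,
    n_points: int = 121,
) -> HysteresisResult:
    """Closure at a hot temperature followed by continued evolution cold.

    Both phases must be non-hydrolysing (AMPPNP gating).  When the cold
    rates are both ≈ 0 the closed fraction reached while hot is retained —
    the kinetic trapping (hysteresis) seen when a slowly-closing protein is
    closed at high temperature and then cooled.
    """
    for name, p in (("hot", params_hot), ("cold", params_cold)):
        if p.k_hyd_effective > 0:
            raise InvalidSpecError(f"hysteresis protocol requires no hydrolysis ({name} phase)")
    t1 = np.linspace(0.0, t_hot, n_points)
    f1, _ = _propagate(0.0, params_hot.k_close_effective, params_hot.k_reopen, 0.0, t1)
    t2 = np.linspace(0.0, t_cold, n_points)[1:]
    f2, _ = _propagate(float(f1[-1]), params_cold.k_close_effective,
                       params_cold.k_reopen, 0.0, t2)
    t = np.concatenate([t1, t_hot + t2])
    f = np.concatenate([f1, f2])
    traj = Trajectory(t=t, f_open=1.0 - f, f_closed=f,
                      atp_turnover=np.zeros_like(t), label="hysteresis")
    return HysteresisResult(
        trajectory=traj,
        f_closed_end_hot=float(f1[-1]),
        f_closed_end_cold=float(f[-1]),
    )
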