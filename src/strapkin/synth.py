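"""Synthetic inputs for every pipeline stage.

The instrument data behind the original TRAP1 experiments are not deposited,
so this module generates stand-ins with the statistical structure the
analyses assume:

* unit-area P(r) distance distributions for an extended "open" dimer and a
  compact "closed" dimer, built by Monte-Carlo sampling of points inside
  simple solids and histogramming pairwise distances (physically shaped
  curves without any atomic-model scattering computation);
* noisy linear open/closed mixtures of those references;
* anti-correlated donor/acceptor FRET channels whose ratio follows a
  single-exponential rise or decay;
* anti-correlated EPR mobile/immobile peak-height time courses sharing one
  rate constant;
* temperature series of rates obeying the Arrhenius law.

Determinism: a fixed :class:`SynthConfig` seed yields byte-identical output.
Random streams are split per output name, so generating one quantity never
perturbs another.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .datatypes import R_KCAL, PrCurve, RateSeries, TimeSeries, celsius_to_kelvin
from .errors import GridMismatchError, InvalidSpecError

__all__ = [
    "SynthConfig",
    "ShapeSpec",
    "make_reference_pr",
    "make_pr_mixture",
    "make_fret_trace",
    "make_epr_timecourse",
    "make_rate_series",
]


def _default_t_grid() -> np.ndarray:
    # 0-240 min at 2-min sampling: covers >6 half-lives of the slowest
    # default rates while staying cheap to fit.
    return np.arange(0.0, 240.0 + 1e-9, 2.0)


@dataclass
class SynthConfig:
    """Shared knobs of all generators.

    ``noise_sd`` is a fraction of the signal amplitude (dimensionless);
    ``t_grid`` is in minutes and must be strictly increasing; ``r_step``
    is the Å bin width of generated P(r) grids.
    """

    seed: int = 0
    noise_sd: float = 0.0
    t_grid: np.ndarray = field(default_factory=_default_t_grid)
    r_step: float = 1.0

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.t_grid.size == 0 or (
            self.t_grid.size > 1 and np.any(np.diff(self.t_grid) <= 0)
        ):
            raise InvalidSpecError("t_grid must be non-empty and strictly increasing")
        if self.r_step <= 0:
            raise InvalidSpecError("r_step must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named output stream.

        The stream name is hashed into the seed sequence, so every named
        quantity draws from its own reproducible stream.
        """
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        )


@dataclass
class ShapeSpec:
    """Geometry of a Monte-Carlo scattering body.

    Both geometries are unions of two equal spheres of radius ``radius``
    whose centres sit ``separation`` Å apart: a large separation gives the
    extended open dimer (dumbbell), a small or zero separation the compact
    closed globule.  ``separation = 0`` degenerates to a single sphere with
    Dmax exactly ``2·radius``.
    """

    geometry: str
    radius: float
    separation: float
    n_samples: int = 4000

    def __post_init__(self):
        if self.geometry not in ("open_dumbbell", "closed_globule"):
            raise InvalidSpecError(f"unknown geometry {self.geometry!r}")
        if self.radius <= 0:
            raise InvalidSpecError("sphere radius must be > 0")
        if self.separation < 0:
            raise InvalidSpecError("separation must be >= 0")
        if self.n_samples < 10:
            raise InvalidSpecError("n_samples too small to histogram")

    @property
    def dmax(self) -> float:
        """Maximum intramolecular distance of the body."""
        return self.separation + 2.0 * self.radius


#: Default open-state geometry: two 25 Å spheres 60 Å apart (Dmax 110 Å).
DEFAULT_OPEN = ShapeSpec("open_dumbbell", radius=25.0, separation=60.0)
#: Default closed-state geometry: two 25 Å spheres nearly merged (Dmax 62 Å).
DEFAULT_CLOSED = ShapeSpec("closed_globule", radius=25.0, separation=12.0)


def _sample_points(spec: ShapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside each of the two spheres (half per sphere)."""
    n1 = spec.n_samples // 2
    pts = []
    for n, offset in ((n1, -spec.separation / 2), (spec.n_samples - n1, spec.separation / 2)):
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = spec.radius * rng.random(n) ** (1.0 / 3.0)
        p = u * radii[:, None]
        p[:, 0] += offset
        pts.append(p)
    return np.vstack(pts)


def _pair_distance_counts(pts: np.ndarray, edges: np.ndarray, block: int = 2000) -> np.ndarray:
    """Histogram of all pairwise distances, computed in blocks.

    Keeps memory at O(block × n) so large samples never materialise the
    full n(n−1)/2 distance vector.
    """
    n = len(pts)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for i in range(0, n, block):
        chunk = pts[i : i + block]
        counts += np.histogram(pdist(chunk), bins=edges)[0]
        if i + block < n:
            counts += np.histogram(cdist(chunk, pts[i + block :]).ravel(), bins=edges)[0]
    return counts


def _histogram_pr(counts: np.ndarray, edges: np.ndarray, label: str) -> PrCurve:
    centers = 0.5 * (edges[:-1] + edges[1:])
    r = np.concatenate(([0.0], centers, [edges[-1]]))
    p = np.concatenate(([0.0], counts.astype(float), [0.0]))
    area = np.trapezoid(p, r)
    return PrCurve(r=r, p=p / area, label=label)


def make_reference_pr(
    open_spec: ShapeSpec = DEFAULT_OPEN,
    closed_spec: ShapeSpec = DEFAULT_CLOSED,
    cfg: SynthConfig | None = None,
) -> tuple[PrCurve, PrCurve]:
    """Build open and closed reference P(r) curves on one shared grid.

    Returns two unit-area curves on a grid running from 0 to the larger of
    the two Dmax values in steps of ``cfg.r_step``.  P(0) and P(Dmax) are
    exactly zero; the open curve has a larger mean distance than the closed
    one whenever its geometry is more extended.
    """
    cfg = cfg or SynthConfig()
    dmax = max(open_spec.dmax, closed_spec.dmax)
    n_bins = int(np.ceil(dmax / cfg.r_step))
    edges = np.linspace(0.0, n_bins * cfg.r_step, n_bins + 1)

    curves = []
    for name, spec in (("pr_open", open_spec), ("pr_closed", closed_spec)):
        pts = _sample_points(spec, cfg.rng(name))
        counts = _pair_distance_counts(pts, edges)
        curves.append(_histogram_pr(counts, edges, label=name.replace("pr_", "")))
    return curves[0], curves[1]


def make_pr_mixture(
    open_ref: PrCurve,
    closed_ref: PrCurve,
    f_closed: float,
    cfg: SynthConfig | None = None,
    stream: str = "pr_mixture",
) -> PrCurve:
    """Linear two-state mixture f·P_closed + (1−f)·P_open with noise.

    Multiplicative Gaussian noise of relative standard deviation
    ``cfg.noise_sd`` mimics count-dominated SAXS error.  The clean mixture
    of unit-area references is itself unit-area.
    """
    if not np.array_equal(open_ref.r, closed_ref.r):
        raise GridMismatchError("open and closed references are on different grids")
    if not 0.0 <= f_closed <= 1.0:
        raise InvalidSpecError("f_closed must be in [0, 1]")
    cfg = cfg or SynthConfig()
    clean = f_closed * closed_ref.p + (1.0 - f_closed) * open_ref.p
    label = f"mixture(f_closed={f_closed:g})"
    if cfg.noise_sd == 0:
        return PrCurve(r=open_ref.r, p=clean, label=label)
    noise = cfg.rng(stream).normal(0.0, cfg.noise_sd, size=clean.shape)
    return PrCurve(
        r=open_ref.r,
        p=clean * (1.0 + noise),
        err=cfg.noise_sd * np.abs(clean),
        label=label,
    )


def make_fret_trace(
    direction: str,
    m1: float,
    m2: float,
    m3: float,
    cfg: SynthConfig | None = None,
    acceptor_rel_change: float = 0.2,
) -> tuple[TimeSeries, TimeSeries]:
    """Anti-correlated donor/acceptor channels with exponential kinetics.

    The donor/acceptor ratio follows ``m1 + m2·(1 − e^{−m3 t})`` for a rise
    or ``m1 + m2·e^{−m3 t}`` for a decay, exactly, before noise.  The
    acceptor changes by the fraction ``acceptor_rel_change`` in the opposite
    sense, and the donor is the product ratio × acceptor, so the two raw
    channels move anti-correlatedly as in a closure experiment.  Additive
    Gaussian noise of sd ``noise_sd × (channel amplitude)`` is applied per
    channel.
    """
    if direction not in ("rise", "decay"):
        raise InvalidSpecError(f"direction must be 'rise' or 'decay', got {direction!r}")
    if m3 <= 0:
        raise InvalidSpecError("rate constant m3 must be > 0")
    cfg = cfg or SynthConfig()
    t = cfg.t_grid
    u = 1.0 - np.exp(-m3 * t)  # 0 -> 1
    ratio = m1 + m2 * u if direction == "rise" else m1 + m2 * (1.0 - u)
    # acceptor moves against the ratio so donor (= ratio * acceptor) and
    # acceptor are anti-correlated
    sign = -1.0 if direction == "rise" else 1.0
    if m2 == 0:
        sign = 0.0
    acceptor = 1.0 + sign * acceptor_rel_change * u
    donor = ratio * acceptor

    out = []
    for name, y in (("donor", donor), ("acceptor", acceptor)):
        noisy = y
        if cfg.noise_sd > 0 and np.ptp(y) > 0:
            noisy = y + cfg.rng(f"fret_{name}").normal(0.0, cfg.noise_sd * np.ptp(y), y.shape)
        out.append(TimeSeries(t=t, y=noisy, channel=name))
    return out[0], out[1]


def make_epr_timecourse(
    k: float,
    amp_mobile: float,
    amp_immobile: float,
    cfg: SynthConfig | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Mobile/immobile EPR peak-height series sharing one rate constant.

    Each channel follows ``amp·(1 − e^{−k t})`` (percent-change convention:
    starts at 0, tends to its amplitude).  Amplitudes are expected to have
    opposite signs — the anti-correlation of the two spectral components;
    same-sign amplitudes are permitted but flagged with a warning.  Noise is
    additive Gaussian with sd ``noise_sd × |amplitude|`` per channel.
    """
    if k <= 0:
        raise InvalidSpecError("rate constant k must be > 0")
    if amp_mobile * amp_immobile > 0:
        warnings.warn("mobile and immobile amplitudes have the same sign", stacklevel=2)
    cfg = cfg or SynthConfig()
    t = cfg.t_grid
    u = 1.0 - np.exp(-k * t)
    out = []
    for name, amp in (("mobile", amp_mobile), ("immobile", amp_immobile)):
        y = amp * u
        if cfg.noise_sd > 0:
            y = y + cfg.rng(f"epr_{name}").normal(0.0, cfg.noise_sd * abs(amp), y.shape)
        out.append(TimeSeries(t=t, y=y, channel=name))
    return out[0], out[1]


def make_rate_series(
    lnA: float,
    Ea: float,
    temps_c: np.ndarray | list[float],
    cfg: SynthConfig | None = None,
    label: str = "",
) -> RateSeries:
    """Arrhenius-law rates k(T) = exp(lnA − Ea/(R·T_K)) with lognormal noise.

    ``Ea`` in kcal/mol, temperatures in °C.  Noise multiplies each rate by
    ``exp(ε)`` with ε ~ N(0, noise_sd), keeping rates positive.
    """
    if Ea < 0:
        raise InvalidSpecError("Ea must be >= 0")
    cfg = cfg or SynthConfig()
    t_k = celsius_to_kelvin(np.asarray(temps_c, dtype=float))
    k = np.exp(lnA - Ea / (R_KCAL * t_k))
    if cfg.noise_sd > 0:
        k = k * np.exp(cfg.rng("rates").normal(0.0, cfg.noise_sd, k.shape))
    return RateSeries(T_C=np.asarray(temps_c, dtype=float), k=k, label=label)
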