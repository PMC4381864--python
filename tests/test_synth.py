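"""Synthetic-data generator: geometry, determinism, noise models and the
exact invertibility of every noise-free output by its downstream fit."""

import numpy as np
import pytest

from strapkin import (
    R_KCAL,
    ShapeSpec,
    SynthConfig,
    arrhenius_fit,
    fit_exponential,
    fret_ratio,
    make_epr_timecourse,
    make_fret_trace,
    make_pr_mixture,
    make_rate_series,
    make_reference_pr,
)
from strapkin.errors import GridMismatchError, InvalidSpecError


# ---------------------------------------------------------------- P(r)

def test_seed_determinism_is_bit_exact():
    a, b = (make_reference_pr(cfg=SynthConfig(seed=7)) for _ in range(2))
    assert np.array_equal(a[0].p, b[0].p) and np.array_equal(a[1].p, b[1].p)
    assert np.array_equal(a[0].r, b[0].r)


def test_reference_curves_are_unit_area_nonnegative_with_zero_endpoints(refs):
    for curve in refs:
        assert np.all(curve.p >= 0)
        assert np.trapezoid(curve.p, curve.r) == pytest.approx(1.0, abs=1e-9)
        assert curve.p[0] == 0.0 and curve.p[-1] == 0.0
    open_c, closed_c = refs
    assert np.array_equal(open_c.r, closed_c.r)
    mean_open = np.trapezoid(open_c.r * open_c.p, open_c.r)
    mean_closed = np.trapezoid(closed_c.r * closed_c.p, closed_c.r)
    assert mean_open > mean_closed
    assert open_c.dmax > closed_c.dmax


def test_identical_specs_give_matching_curves_within_mc_noise():
    spec = ShapeSpec("open_dumbbell", radius=20.0, separation=40.0, n_samples=4000)
    a, b = make_reference_pr(spec, spec, SynthConfig(seed=3))
    # different MC streams, same geometry: small L1 discrepancy only
    assert np.trapezoid(np.abs(a.p - b.p), a.r) < 0.1


def test_single_sphere_support_ends_at_twice_radius():
    sphere = ShapeSpec("closed_globule", radius=15.0, separation=0.0, n_samples=3000)
    _, curve = make_reference_pr(ShapeSpec("open_dumbbell", 15.0, 10.0), sphere,
                                 SynthConfig(seed=1, r_step=0.5))
    assert curve.r[np.abs(curve.p) > 0].max() <= 2 * 15.0


def test_dumbbell_second_mode_matches_bruteforce_histogram():
    """Well-separated dumbbell: bimodal P(r) with the far mode near the
    centre separation, cross-checked against an independently sampled
    brute-force pairwise-distance histogram."""
    d, a = 100.0, 10.0
    spec = ShapeSpec("open_dumbbell", radius=a, separation=d, n_samples=4000)
    curve, _ = make_reference_pr(spec, ShapeSpec("closed_globule", a, 0.0, n_samples=100),
                                 SynthConfig(seed=5, r_step=2.0))
    far = curve.r > d / 2
    mode_pkg = curve.r[far][np.argmax(curve.p[far])]

    # independent oracle: rejection-sample points in the two balls, O(n^2) loop
    rng = np.random.default_rng(99)
    pts = []
    centers = (-d / 2, d / 2)
    while len(pts) < 600:
        p = rng.uniform(-a, a, 3)
        if p @ p <= a * a:
            c = centers[len(pts) % 2]
            pts.append([p[0] + c, p[1], p[2]])
    pts = np.asarray(pts)
    dists = [
        float(np.linalg.norm(pts[i] - pts[j]))
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
    ]
    counts, edges = np.histogram(dists, bins=np.arange(0.0, d + 2 * a + 2.0, 2.0))
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    far_o = centers_r > d / 2
    mode_oracle = centers_r[far_o][np.argmax(counts[far_o])]

    assert abs(mode_pkg - d) < 6.0
    assert abs(mode_pkg - mode_oracle) < 6.0


def test_degenerate_geometry_rejected():
    with pytest.raises(InvalidSpecError):
        ShapeSpec("open_dumbbell", radius=0.0, separation=10.0)
    with pytest.raises(InvalidSpecError):
        ShapeSpec("banana", radius=5.0, separation=10.0)


def test_quadrupling_samples_halves_l1_distance_to_large_sample_reference():
    """Monte-Carlo convergence: pairwise-distance histograms from n points
    converge as 1/√n (each point enters ~n pairs, so pair counts are
    correlated), hence quadrupling n_samples halves the L1 distance to a
    much larger-sample reference, within ±50%."""
    closed = ShapeSpec("closed_globule", 25.0, 12.0, n_samples=100)

    def open_curve(n, seed):
        o, _ = make_reference_pr(
            ShapeSpec("open_dumbbell", 25.0, 60.0, n_samples=n), closed,
            SynthConfig(seed=seed))
        return o

    ref = open_curve(20000, 999)
    ratios = []
    for seed in range(8):
        d1 = np.trapezoid(np.abs(open_curve(1000, seed).p - ref.p), ref.r)
        d2 = np.trapezoid(np.abs(open_curve(4000, seed + 100).p - ref.p), ref.r)
        ratios.append(d2 / d1)
    assert 0.25 <= np.mean(ratios) <= 0.75


# ---------------------------------------------------------------- mixtures

def test_mixture_endpoints_and_linearity(open_ref, closed_ref):
    cfg = SynthConfig(seed=0, noise_sd=0.0)
    assert np.array_equal(
        make_pr_mixture(open_ref, closed_ref, 0.0, cfg).p, open_ref.p)
    assert np.array_equal(
        make_pr_mixture(open_ref, closed_ref, 1.0, cfg).p, closed_ref.p)
    half = make_pr_mixture(open_ref, closed_ref, 0.5, cfg)
    np.testing.assert_allclose(half.p, 0.5 * (open_ref.p + closed_ref.p), atol=1e-15)


def test_mixture_requires_shared_grid(open_ref, closed_ref):
    from strapkin.datatypes import PrCurve
    shifted = PrCurve(r=closed_ref.r + 0.5, p=closed_ref.p)
    with pytest.raises(GridMismatchError):
        make_pr_mixture(open_ref, shifted, 0.5)


# ---------------------------------------------------------------- FRET

def test_fret_ratio_hits_half_amplitude_at_half_life():
    m1, m2, m3 = 1.0, 0.5, 0.02
    t_half = np.log(2.0) / m3
    cfg = SynthConfig(seed=0, noise_sd=0.0, t_grid=[0.0, 10.0, t_half, 60.0])
    donor, acceptor = make_fret_trace("rise", m1, m2, m3, cfg)
    ratio = fret_ratio(donor, acceptor)
    assert ratio.y[2] == pytest.approx(m1 + m2 / 2, abs=1e-12)


def test_fret_zero_amplitude_gives_constant_channels():
    donor, acceptor = make_fret_trace("rise", 1.0, 0.0, 0.02,
                                      SynthConfig(seed=0, noise_sd=0.05))
    assert np.ptp(donor.y) == 0.0 and np.ptp(acceptor.y) == 0.0


def test_fret_channels_anticorrelated_and_ratio_exact():
    cfg = SynthConfig(seed=0, noise_sd=0.0)
    for direction in ("rise", "decay"):
        donor, acceptor = make_fret_trace(direction, 1.0, 0.5, 0.05, cfg)
        d_dir = np.sign(donor.y[-1] - donor.y[0])
        a_dir = np.sign(acceptor.y[-1] - acceptor.y[0])
        assert d_dir * a_dir == -1.0
        ratio = fret_ratio(donor, acceptor)
        t = cfg.t_grid
        expect = (1.0 + 0.5 * (1 - np.exp(-0.05 * t)) if direction == "rise"
                  else 1.0 + 0.5 * np.exp(-0.05 * t))
        np.testing.assert_allclose(ratio.y, expect, rtol=1e-12)


def test_fret_rejects_nonpositive_rate():
    with pytest.raises(InvalidSpecError):
        make_fret_trace("rise", 1.0, 0.5, 0.0)


def test_fret_rate_recovery_under_noise():
    """Noisy generator traces are inverted by the exponential fit: mean
    recovered rate within 5% of the generating 0.02 min^-1 over 20 seeds."""
    recovered = []
    for seed in range(20):
        donor, acceptor = make_fret_trace(
            "rise", 1.0, 0.5, 0.02, SynthConfig(seed=seed, noise_sd=0.02))
        recovered.append(fit_exponential(fret_ratio(donor, acceptor), "rise").m3)
    assert abs(np.mean(recovered) - 0.02) / 0.02 < 0.05


# ---------------------------------------------------------------- EPR

def test_epr_channels_share_kinetics_exactly():
    cfg = SynthConfig(seed=0, noise_sd=0.0, t_grid=np.arange(0.0, 200.0, 5.0))
    mobile, immobile = make_epr_timecourse(0.05, -80.0, 100.0, cfg)
    np.testing.assert_allclose(mobile.y / -80.0, immobile.y / 100.0, rtol=1e-12)


def test_epr_half_life():
    k = 0.014
    t_half = np.log(2.0) / k
    cfg = SynthConfig(seed=0, noise_sd=0.0, t_grid=[0.0, t_half, 300.0])
    mobile, immobile = make_epr_timecourse(k, -100.0, 100.0, cfg)
    assert mobile.y[1] == pytest.approx(-50.0, abs=1e-9)
    assert immobile.y[1] == pytest.approx(50.0, abs=1e-9)


def test_epr_same_sign_amplitudes_warn():
    with pytest.warns(UserWarning):
        make_epr_timecourse(0.05, 50.0, 100.0, SynthConfig(seed=0))


# ---------------------------------------------------------------- rates

def test_rate_series_flat_when_ea_zero():
    rs = make_rate_series(lnA=1.3, Ea=0.0, temps_c=[10.0, 25.0, 40.0])
    np.testing.assert_allclose(rs.k, np.exp(1.3), rtol=1e-12)


def test_noise_free_rates_invert_exactly():
    rs = make_rate_series(lnA=75.0, Ea=48.8, temps_c=[23.0, 30.0, 36.0, 42.0])
    fit = arrhenius_fit(rs)
    assert fit.Ea == pytest.approx(48.8, rel=1e-9)
    assert fit.lnA == pytest.approx(75.0, rel=1e-9)


def test_activation_energy_sets_fold_drop_between_temperatures():
    """The relative fold-change between a steep (48.8 kcal/mol) and a
    shallow (29) series over 23→42 °C follows exp(ΔEa·Δ(1/T)/R)."""
    temps = [23.0, 42.0]
    steep = make_rate_series(lnA=75.0, Ea=48.8, temps_c=temps)
    shallow = make_rate_series(lnA=45.0, Ea=29.0, temps_c=temps)
    fold_steep = steep.k[1] / steep.k[0]
    fold_shallow = shallow.k[1] / shallow.k[0]
    delta_inv_t = 1 / (23.0 + 273.15) - 1 / (42.0 + 273.15)
    expect = np.exp((48.8 - 29.0) * delta_inv_t / R_KCAL)
    assert fold_steep / fold_shallow == pytest.approx(expect, rel=1e-9)
    assert expect == pytest.approx(7.60, abs=0.05)
    # consistent with the measured fold ladder: 24-fold at 23 °C vs
    # 3-fold at 42 °C gives a ratio of fold-changes near the same value
    assert (24.333 / 3.097) == pytest.approx(expect, rel=0.1)


def test_rate_series_rejects_bad_inputs():
    with pytest.raises(InvalidSpecError):
        make_rate_series(lnA=1.0, Ea=-5.0, temps_c=[20.0])
    with pytest.raises(InvalidSpecError):
        SynthConfig(seed=0, noise_sd=-0.1)
    with pytest.raises(InvalidSpecError):
        SynthConfig(seed=0, t_grid=[3.0, 2.0])
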