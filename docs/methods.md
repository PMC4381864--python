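# Methods

## The system and the observables

TRAP1, the mitochondrial Hsp90 paralog, is a homodimer whose ATPase cycle
passes through a slow, strongly temperature-dependent transition from an
extended open state to a compact closed state in which the N-terminal
domains dimerise. Three experimental readouts report on this transition and
each has a corresponding analysis in this package: small-angle X-ray
scattering (the pair-distance distribution P(r) compactifies on closure),
FRET between probes on the two protomers (anti-correlated donor/acceptor
changes), and CW-EPR of a lid-attached spin probe (mobile and immobile
spectral components exchanging with one rate). A fourth module composes the
measured rate constants into a kinetic model of the full cycle.

## Two-state P(r) decomposition

An observed P(r) is fit as a non-negative linear combination of an open and
a closed reference curve. Choices that were genuinely open, and how they
were made:

* **R factor.** Fit quality is reported as
  `R = Σ_r |P_obs − P_calc| / Σ_r |P_obs|` — the crystallographic-R reading
  of a normalised absolute deviation. A strictly pointwise mean of
  `|ΔP|/|P_obs|` diverges wherever P(r) approaches zero (which it does at
  both ends of its support by construction) and is therefore not the
  default; it remains available via `r_merge(..., pointwise=True)`.
* **Non-negativity.** Coefficients are constrained ≥ 0 (scipy NNLS): P(r)
  components are densities and negative occupancies are unphysical. The
  reported fraction is `c_closed/(c_open+c_closed)`, so any overall scale
  error in the observation cancels.
* **Normalisation.** Observed and reference curves are trapezoid-normalised
  to unit area before fitting, which makes the coefficient ratio an exact
  population fraction. Raw coefficients are reported too
  (`normalize=False` skips the normalisation).
* **Fit region.** Points enter the fit where both the observation and the
  closed reference exceed 10⁻⁴ of their own maxima. This mirrors fitting
  "where non-zero data are present" while keeping the threshold explicit
  and configurable; the long-r tail beyond the closed state's Dmax (where
  only the open reference has support) is excluded.
* **Interpolation.** References are linearly interpolated onto the observed
  grid; observed data are never resampled.

The analytic fit is verified in the test suite against a brute-force grid
search over the closed fraction (step 10⁻⁴, optimal overall scale solved in
closed form per candidate), and the two agree to 10⁻³ everywhere tested.

## Exponential kinetics

FRET ratio traces are fit to `m1 + m2·(1 − e^{−m3 t})` (rise) or
`m1 + m2·e^{−m3 t}` (decay); `m3` is the rate constant in min⁻¹.
Initialisation is parameter-free: `m1` from the first observation, `m2`
from last − first, `m3` as ln 2 over the first time the signal crosses half
its total change (first crossing breaks ties in noisy data). Least squares
is unweighted — no error model is assumed for y — with relative parameter
tolerance 10⁻⁸ and at most 10⁴ objective evaluations; non-convergence sets
a flag rather than raising. A series whose total change is below three
times a robust noise floor (median absolute second difference, scaled) is
rejected as non-identifiable instead of returning a meaningless rate.

EPR peak heights are first converted to percent change over the time
course, `PC(t) = 100·(y(t) − y(t₀))/|y(t_end) − y(t₀)|`, using the realised
endpoints rather than a fitted asymptote (no prior fit required; a
fitted-asymptote variant is not provided because percent change is an
affine map and thus rate-preserving either way). The mobile and immobile
series are then fit jointly as `amp·(1 − e^{−k t})` per channel under one
shared rate constant, offsets fixed at zero as appropriate for
percent-change data (`fit_offsets=True` floats them). Forcing the shared
rate onto channels with genuinely different kinetics measurably raises the
joint residual, which the tests assert.

**Units.** Time is minutes everywhere internally and rates are min⁻¹;
file readers accept `time_unit="s"` and convert on ingest, and CLI reports
emit a secondary s⁻¹ column. This keeps one unambiguous internal unit while
accommodating data logged in seconds.

## Arrhenius analysis and rate-ratio thermodynamics

`ln k` is regressed on `1/T_K` by ordinary least squares (no error
propagation into the regression, since replicate errors on the rates are
not modelled); `Ea = −slope·R` with `R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹` and
`T_K = T_°C + 273.15`. On the tabulated closure rates this gives
49.1 kcal/mol (wild type) and 28.8 kcal/mol (strap deletion), a ~20 kcal/mol
difference: the strap contributes about half the closure barrier. Because
"the strap contributes X% of the barrier" admits two readings
((Ea_wt−Ea_del)/Ea_wt ≈ 41% vs Ea_del/Ea_wt ≈ 59%), both ratios are
returned by `strap_fraction_of_ea` and neither is privileged.

`ΔΔG‡ = R·T_K·ln(k₂/k₁)` converts rate ratios to barrier-height
differences at the experiment temperature of the pair (30 °C for the
closure/reopening comparisons). Fold changes carry both the raw ratio and a
round-half-up integer presentation value, matching how such numbers are
quoted in prose.

## Cycle model

States are lumped to the two the observables distinguish: "open" (apo,
ATP-bound pre-closure, and post-hydrolysis species) and "closed"
(N-terminally dimerised). Transitions: open→closed at `k_close` (optionally
Arrhenius-parameterised), closed→open at `k_reopen`, and closed→open with
hydrolysis at `k_hyd`, which is gated to zero unless ATP and Mg²⁺ are both
present (AMPPNP always gates it off). Rebinding after an ADP chase is
neglected (large ADP excess), so the observed reopening rate is `k_reopen`
itself. ATP turnover counts cycle completions with a configurable
ATP-per-cycle multiplier defaulting to 1; whether two ATP are consumed per
dimer cycle is deliberately not asserted.

Occupancies follow the closed form
`f_closed(t) = f_∞ + (f₀ − f_∞)·e^{−λt}` with `λ` the sum of active rates
and `f_∞ = k_close/λ`; the Mg²⁺-jump protocol composes two such phases.
Trajectories agree with an independent stiff-ODE integration to 10⁻⁶.
The stochastic engine advances a finite population with the exact
per-interval transition probabilities of the two-state Markov chain
(binomial draws — exact at the grid times, not an Euler approximation);
cumulative hydrolysis events are drawn Poisson with mean
`k_hyd·∫n_closed dt` estimated from the realised occupancy, an
approximation that does not affect the occupancy statistics.

With the measured 25 °C ATP rates (`k_close = 0.19`, `k_hyd = 4.3` min⁻¹)
the post-jump steady state is `0.19/(0.19+4.3) ≈ 0.042` closed —
predominantly open — and the sequential-step effective turnover
`1/(1/k_close + 1/k_hyd) = 0.182 min⁻¹` is pinned near `k_close`: closure
is rate-limiting. The measured steady-state ATPase of the same construct
at 30 °C (0.79 min⁻¹) is about twice the sequential-step composition of
the 30 °C rates (0.42, 7.56 → 0.40 min⁻¹), consistent with — but not
proof of — two ATP hydrolysed per dimer cycle; the package surfaces this
only as a diagnostic comparison.

## Synthetic data

The generators reproduce the statistical structure each analysis assumes,
not the instruments:

* **P(r) curves** come from Monte-Carlo sampling of points inside unions of
  two equal spheres (radius 25 Å; centre separation 60 Å for the open
  dumbbell, 12 Å for the compact closed body — dimensions on the scale of a
  chaperone dimer, giving Dmax 110 vs 62 Å) and histogramming pairwise
  distances in 1 Å bins. This yields physically shaped, unit-area curves
  with P(0) = P(Dmax) = 0 without any atomic-model scattering computation.
  Convergence note: pair-distance histograms from n points converge as
  1/√n, not 1/n — the ~n²/2 pair distances are correlated because each
  point enters ~n pairs — so quadrupling `n_samples` halves the Monte-Carlo
  error (the suite tests exactly this).
* **Noise models.** Multiplicative Gaussian for P(r) (relative sd default
  0.01, mimicking count-dominated scattering error; the true instrument
  error model is not published, so this is a stand-in, not a claim),
  additive Gaussian scaled to channel amplitude for FRET (default 0.02)
  and EPR (0.02), lognormal for Arrhenius rate tables.
* **Determinism.** A `SynthConfig` seed makes every output bit-reproducible,
  and random streams are split per output name (seed sequence keyed by a
  CRC of the stream name), so generating one quantity never shifts another.
* Every generator's noise-free output is exactly inverted by its downstream
  fit; the tests assert this for each pair.

**What passing tests do and do not show.** Synthetic mixtures are built
from the same reference curves the fit uses, so recovery accuracy here
bounds only the statistical error of the decomposition, not systematic
error from imperfect references (e.g. a theoretical closed-state model
differing from the true closed ensemble) — with 1% noise the synthetic R
factors (~0.006–0.010) sit at or below the 0.010–0.042 range typical of
fits to real data for exactly that reason. Likewise the FRET/EPR
generators assume ideal single-exponential kinetics with stationary noise;
photobleaching, drift, or multi-phasic kinetics would need models this
package deliberately omits.

## Problem sizes and numerical defaults

Reference P(r) curves default to 4 000 Monte-Carlo points (pairwise
distances histogrammed in bounded-memory blocks); recovery statistics use
20 noise realisations per condition; stochastic cycle runs use 10⁴ dimers.
These sizes make every headline number reproducible in seconds on a single
core while keeping Monte-Carlo error well inside the tolerances being
tested. Degenerate inputs (zero-area curves, constant time series, all-equal
temperatures, zero rates) raise typed errors rather than returning silent
values; tie-breaking for the half-change initialisation uses the first
crossing.

## Known limitations

* No indirect Fourier transform from I(q), no Dmax optimisation, and no
  theoretical scattering from atomic coordinates — P(r) curves are parsed
  or generated, never derived from scattering intensities.
* Two states only; no multi-component P(r) decomposition.
* Single-exponential kinetics only; no stretched or multi-exponential
  models, no photobleaching correction, no EPR lineshape simulation (peak
  heights are taken as given).
* No Eyring decomposition of the barrier into ΔH‡/ΔS‡ and no
  error-in-variables regression.
* The cycle model omits the asymmetric intermediate and client/cochaperone
  effects; sub-step rates are not resolved by the available observables.
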