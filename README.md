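# strapkin

Quantitative analysis of the open → closed conformational cycle of
Hsp90-family chaperones, built around the mitochondrial paralog TRAP1.
TRAP1 is a homodimer whose ATPase cycle requires a large rearrangement
from an extended open state to a compact, N-terminally dimerised closed
state; an N-terminal "strap" extension makes that closure unusually slow
and temperature-sensitive. `strapkin` implements the analysis layer such
experiments need:

* **SAXS two-state decomposition** — a measured pair-distance distribution
  P(r) is modelled as a non-negative linear combination of an open and a
  closed reference curve, `P_obs ≈ c_o·P_open + c_c·P_closed`, reporting the
  closed-state population `c_c/(c_o+c_c)` and a crystallographic-style R
  factor `R = Σ|P_obs − P_calc| / Σ|P_obs|`. GNOM `.out` files and plain
  P(r) tables are read directly.
* **Exponential kinetics** — single-exponential rise
  `m1 + m2·(1 − e^{−m3·t})` and decay `m1 + m2·e^{−m3·t}` fits of FRET
  ratio traces; percent-change normalisation of EPR peak heights and a
  constrained joint fit of the mobile/immobile components under one shared
  rate constant; area normalisation of steady-state scans.
* **Arrhenius analysis** — `ln k = ln A − Ea/(R·T)` regressions, activation
  energy differences, fold-change tables, and barrier-height differences
  from rate ratios via transition-state theory, `ΔΔG‡ = R·T·ln(k₂/k₁)`.
* **Cycle simulator** — a Mg²⁺-gated kinetic scheme
  (open → closed at `k_close`; closed → open at `k_reopen`; hydrolysis at
  `k_hyd`, only with ATP + Mg²⁺), with exact closed-form trajectories, a
  stochastic finite-population engine, and protocols for the
  Mg²⁺-decoupling and heat-then-cool (kinetic trapping) experiments.
* **Synthetic data** — seeded generators for every input class (Monte-Carlo
  P(r) curves from simple solids, anti-correlated FRET/EPR channels,
  Arrhenius rate tables), so the whole pipeline is testable end to end
  without instrument data.

The library is the primary interface; `examples/` holds one short script
per capability, and a thin `strapkin` command-line tool wraps the stages
(`simulate`, `saxs-fit`, `fret-fit`, `epr-fit`, `arrhenius`, `cycle`,
`demo`) for shell pipelines.

## Worked example

```python
from strapkin import SynthConfig, fit_two_state, make_pr_mixture, make_reference_pr

cfg = SynthConfig(seed=0, noise_sd=0.01)
open_ref, closed_ref = make_reference_pr(cfg=cfg)
mixture = make_pr_mixture(open_ref, closed_ref, f_closed=0.84, cfg=cfg)
fit = fit_two_state(mixture, open_ref, closed_ref)
print(f"{fit.percent_closed:.1f}%  R = {fit.r_merge:.4f}")
```

prints

```
83.9%  R = 0.0087
```

— the decomposition recovers the generating 84% closed population (the
value measured for the wild-type human protein at 43 °C) to within the
noise, and the R factor says the two-state model leaves <1% unexplained
absolute deviation. Running `python examples/arrhenius_strap_contribution.py`
prints the activation energies computed from the tabulated closure rates:

```
Ea (WT):       49.1 kcal/mol  (r^2 = 0.997)
Ea (no strap): 28.8 kcal/mol  (r^2 = 0.962)
strap contribution to the barrier: 20.3 kcal/mol
```

i.e. removing the strap halves the closure barrier, which is why strap
deletion accelerates closure 24-fold at 23 °C but only 3-fold at 42 °C.

## Layout

```
src/strapkin/    synth.py (generators)  saxs.py (P(r) decomposition)
                 kinetics.py (exponential fits)  thermal.py (Arrhenius, ΔΔG)
                 cycle.py (cycle simulator)  io.py (formats)  cli.py
                 literature.py (published rate tables used as inputs)
examples/        one narrative script per capability
docs/methods.md  models, assumptions, parameter choices, limitations
```
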