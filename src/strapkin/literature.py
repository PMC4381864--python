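"""Published TRAP1 kinetic quantities used as analysis inputs.

These are the literature-reported rate constants and populations for human
(hTRAP1) and zebrafish (zTRAP1) mitochondrial Hsp90 constructs: FRET-probed
closure and reopening rates across temperature, steady-state ATPase rates,
ATP-driven closure/hydrolysis rates from the Mg²⁺-decoupling experiment,
SAXS closed-state populations, and the EPR lid-closure rates.  All rates
are in min⁻¹ and temperatures in °C.

They serve as *inputs* to the package's arithmetic — Arrhenius fits, fold
changes, ΔΔG‡, cycle simulations — the way a user would type them in from
a results table.
"""

from __future__ import annotations

import numpy as np

from .datatypes import RateSeries

#: Temperatures (°C) of the closure-rate series measured by inter-protomer FRET.
CLOSURE_TEMPS_C = [23.0, 30.0, 32.0, 36.0, 42.0]

#: WT hTRAP1 closure rates (min⁻¹) by inter-protomer FRET, AMPPNP.
WT_CLOSURE = RateSeries(
    T_C=CLOSURE_TEMPS_C,
    k=[0.003, 0.02, 0.039, 0.118, 0.431],
    label="WT hTRAP1 (inter-FRET)",
)

#: N-terminal strap double-deletion closure rates (min⁻¹), same probe.
DSTRAP_CLOSURE = RateSeries(
    T_C=CLOSURE_TEMPS_C,
    k=[0.073, 0.31, 0.456, 0.853, 1.335],
    label="Δstrap double (inter-FRET)",
)

#: Reopening rates after an ADP chase at 30 °C (min⁻¹).
K_REOPEN_WT_30C = 0.0021
K_REOPEN_DSTRAP_30C = 0.016

#: Closure rates at 30 °C entering the strap ΔΔG‡ comparison (min⁻¹).
K_CLOSE_WT_30C = 0.02
K_CLOSE_DSTRAP_30C = 0.31

#: Steady-state ATPase, hTRAP1 at 30 °C (min⁻¹).
ATPASE_WT_HTRAP1_30C = 0.463
ATPASE_DSTRAP_HTRAP1_30C = 13.3

#: Mg²⁺-decoupling experiment with ATP: hydrolysis rates at 30 °C (min⁻¹).
K_HYD_WT_30C = 7.56
K_HYD_DSTRAP_30C = 10.6
#: Closure under ATP at 30 °C for the cysteine-free FRET construct (min⁻¹).
K_CLOSE_WT_ATP_30C = 0.42

#: Same experiment at 25 °C (min⁻¹); the pair behind the rate-limiting-step
#: assignment (closure ≈ 0.003 s⁻¹, hydrolysis ≈ 0.07 s⁻¹).
K_CLOSE_WT_ATP_25C = 0.19
K_HYD_WT_25C = 4.3

#: SAXS two-state decomposition: percent closed for WT hTRAP1 at 43 °C
#: under AMPPNP (the near-saturated high-temperature point).
PERCENT_CLOSED_WT_43C = 84.0

#: EPR lid-closure shared rate constants at ~23 °C (min⁻¹).
EPR_K_WT = 0.014
EPR_K_DSTRAP = 0.075

#: Reported activation energies (kcal/mol) from the closure-rate Arrhenius
#: plots, for comparison with values recomputed here.
EA_WT_REPORTED = 48.8
EA_DSTRAP_REPORTED = 29.0
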