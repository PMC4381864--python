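"""Mg2+-decoupling experiment on the open/closed ATPase cycle.

With ATP but no Mg2+, the dimer closes and accumulates in the closed state
(hydrolysis is gated off). Adding Mg2+ at 30 min opens the hydrolysis
channel: the population relaxes quickly toward a cycling steady state that
is predominantly open, because closure (0.19 min^-1 at 25 C) is far slower
than hydrolysis (4.3 min^-1) — closure is the rate-limiting step.
"""

import numpy as np

from strapkin import CycleParams, effective_turnover, simulate_mg_jump
from strapkin import literature as lit

params = CycleParams(k_close=lit.K_CLOSE_WT_ATP_25C, k_reopen=0.0,
                     k_hyd=lit.K_HYD_WT_25C, nucleotide="ATP", T_C=25.0)
t = np.linspace(0.0, 90.0, 361)
traj = simulate_mg_jump(params, t_mg=30.0, t_grid=t)

i_jump = np.searchsorted(t, 30.0)
print(f"f_closed just before Mg2+ addition: {traj.f_closed[i_jump]:.3f}")
print(f"f_closed steady state after:        {traj.f_closed[-1]:.3f}")
print(f"ATP turned over by 90 min:          {traj.atp_turnover[-1]:.1f} per dimer")
print(f"effective cycle rate: "
      f"{effective_turnover(params.k_close, params.k_hyd):.3f} min^-1")
# The near-complete closed accumulation before the jump and the ~0.04
# steady-state closed fraction after it show hydrolysis and closure cleanly
# decoupled; the effective cycle rate is pinned near k_close.
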