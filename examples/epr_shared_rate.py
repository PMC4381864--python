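"""Joint fit of EPR mobile/immobile peak heights with one shared rate.

The two spectral components of a lid-attached spin probe change
anti-correlatedly as the lid closes; both are governed by the same
kinetic process, so the fit constrains one rate constant across channels.
Generating value: 0.014 min^-1, the wild-type lid-closure rate.
"""

import numpy as np

from strapkin import SynthConfig, fit_epr_joint, make_epr_timecourse

cfg = SynthConfig(seed=2, noise_sd=0.02, t_grid=np.arange(0.0, 301.0, 5.0))
mobile, immobile = make_epr_timecourse(k=0.014, amp_mobile=-100.0,
                                       amp_immobile=100.0, cfg=cfg)
fit = fit_epr_joint(mobile, immobile)

print(f"shared rate constant: {fit.k_shared:.4f} min^-1  (generating value 0.0140)")
print(f"mobile amplitude:     {fit.amp_mobile:.1f}%")
print(f"immobile amplitude:   {fit.amp_immobile:.1f}%")
# Equal-magnitude, opposite-sign amplitudes with one rate constant are the
# signature of a concerted two-state exchange between the lid environments.
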