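"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from strapkin import normalize_pr
from strapkin.saxs import NONZERO_FRACTION


def grid_search_fraction(obs, open_ref, closed_ref, step=1e-4):
    """Brute-force 1-D search over the closed fraction, minimising the same
    residual as the analytic two-state fit (optimal overall scale solved
    per candidate fraction)."""
    obs = normalize_pr(obs)
    open_p = np.interp(obs.r, open_ref.r, normalize_pr(open_ref).p, left=0, right=0)
    closed_p = np.interp(obs.r, closed_ref.r, normalize_pr(closed_ref).p, left=0, right=0)
    mask = (np.abs(obs.p) > NONZERO_FRACTION * np.max(np.abs(obs.p))) & (
        np.abs(closed_p) > NONZERO_FRACTION * np.max(np.abs(closed_p)))
    y, o, c = obs.p[mask], open_p[mask], closed_p[mask]
    fs = np.arange(0.0, 1.0 + step / 2, step)
    mixes = np.outer(fs, c) + np.outer(1.0 - fs, o)
    scales = np.clip((mixes @ y) / np.einsum("ij,ij->i", mixes, mixes), 0.0, None)
    resid = np.sum((y[None, :] - scales[:, None] * mixes) ** 2, axis=1)
    return fs[np.argmin(resid)]
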