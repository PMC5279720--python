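"""Numerical inner loops for pair-force assembly.

A numba-compiled serial loop over the element pair list; falls back to the
vectorised numpy path in :mod:`rhombosim.scem_mechanics` when numba is not
importable.  The loop is strictly serial so force summation order (and hence
bit-level reproducibility) is independent of threading.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def pair_forces_kernel(
    pos,
    iarr,
    jarr,
    cell_of,
    phi,
    intra_depth,
    intra_req,
    intra_a,
    adh_depth,
    adh_req,
    adh_a,
    rep_amp,
    rep_range,
    cutoff,
    strength_scale,
    out,
):
    n_zero = 0
    r_t = 0.95 * cutoff
    inv_taper = 1.0 / (cutoff - r_t)
    for k in range(len(iarr)):
        i = iarr[k]
        j = jarr[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = np.sqrt(dx * dx + dy * dy)
        if r <= 0.0:
            n_zero += 1
            continue
        if r >= cutoff:
            continue
        if r <= r_t:
            w = 1.0
        else:
            w = (cutoff - r) * inv_taper
        ci = cell_of[i]
        cj = cell_of[j]
        if ci == cj:
            s = (r - intra_req) / intra_a
            f = (2.0 * intra_depth / intra_a) * (np.exp(-2.0 * s) - np.exp(-s))
        else:
            p = phi[ci] * phi[cj]
            f = 0.0
            if p > 0.0:
                s = (r - adh_req) / adh_a
                f += p * (2.0 * adh_depth / adh_a) * (np.exp(-2.0 * s) - np.exp(-s))
            elif p < 0.0:
                f += (-p) * (rep_amp / rep_range) * np.exp(-r / rep_range)
            f *= strength_scale
        f *= w / r
        fx = f * dx
        fy = f * dy
        out[i, 0] += fx
        out[i, 1] += fy
        out[j, 0] -= fx
        out[j, 1] -= fy
    return n_zero
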