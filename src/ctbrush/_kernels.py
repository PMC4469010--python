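"""Compiled inner loops for MART sweeps over large ray systems.

The ray system is stored CSR-style: ``indices`` holds the flat pixel
indices of every ray back to back, ``indptr[j]:indptr[j+1]`` delimits
ray j, and ``targets[j]`` is its measured raysum.  A sweep applies the
multiplicative update ray by ray in order, exactly as the object-level
API does one ray at a time.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: floor of the denominator in relative residuals
EPS = 1e-12


@njit(cache=True)
def mart_sweep(est, indices, indptr, targets):
    """One in-place multiplicative pass over all rays, in order.

    Returns (skipped, max_rel_residual) where the residual of each ray
    is measured just before its own update (the sequential MART
    residual) and ``skipped`` counts rays with a zero current raysum but
    a positive target, which are left untouched.
    """
    n_rays = targets.size
    skipped = 0
    max_res = 0.0
    for j in range(n_rays):
        lo, hi = indptr[j], indptr[j + 1]
        s = 0.0
        for i in range(lo, hi):
            s += est[indices[i]]
        t = targets[j]
        denom = t if t > EPS else EPS
        res = abs(s - t) / denom
        if res > max_res:
            max_res = res
        if t == 0.0:
            for i in range(lo, hi):
                est[indices[i]] = 0.0
        elif s <= 0.0:
            skipped += 1
        else:
            f = t / s
            for i in range(lo, hi):
                est[indices[i]] *= f
    return skipped, max_res


@njit(cache=True)
def max_residual(est, indices, indptr, targets):
    """Max relative raysum residual of the current estimate."""
    n_rays = targets.size
    max_res = 0.0
    for j in range(n_rays):
        lo, hi = indptr[j], indptr[j + 1]
        s = 0.0
        for i in range(lo, hi):
            s += est[indices[i]]
        t = targets[j]
        denom = t if t > EPS else EPS
        res = abs(s - t) / denom
        if res > max_res:
            max_res = res
    return max_res
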