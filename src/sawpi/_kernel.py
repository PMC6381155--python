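"""Numba-compiled inner loop for Monte-Carlo growth trials.

The kernel replays a batch of orientation-choice sequences through the
two-front growth rules and records, per trial, the step at which each front
became blocked (0 = still active at the horizon).  It mirrors
:func:`sawpi.hexgrowth.step_lite` exactly — the pure-Python transition is the
reference, and the test suite checks the two agree sequence-by-sequence.

Occupancy uses a trial-stamped grid instead of a per-trial reset: a cell is
occupied for trial ``t`` iff its stamp equals ``t + 1``, so the grid is
allocated once for the whole batch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["block_steps"]


@njit(cache=True, inline="always")
def _neighbor_at(u, v, s, angle):
    # A-site arms point at 0/120/240 degrees, B-site arms at 180/300/60.
    if s == 0:
        if angle == 0:
            return u, v, 1
        if angle == 120:
            return u - 1, v, 1
        return u, v - 1, 1
    if angle == 180:
        return u, v, 0
    if angle == 300:
        return u + 1, v, 0
    return u, v + 1, 0


@njit(cache=True, inline="always")
def _angle_to(u, v, s, nu, nv):
    # Angle of the arm of (u, v, s) pointing at the neighbouring site (nu, nv).
    if s == 0:
        if nu == u and nv == v:
            return 0
        if nu == u - 1 and nv == v:
            return 120
        return 240
    if nu == u and nv == v:
        return 180
    if nu == u + 1 and nv == v:
        return 300
    return 60


@njit(cache=True)
def _block_steps(lo, ro):
    n_trials, n_steps = lo.shape
    out = np.zeros((n_trials, 2), dtype=np.int32)
    off = n_steps + 2
    dim = 2 * n_steps + 5
    stamp = np.zeros(dim * dim * 2, dtype=np.int64)
    fr = np.zeros((2, 7), dtype=np.int64)  # au, av, as, tu, tv, ts, active
    for t in range(n_trials):
        tid = t + 1
        stamp[(off * dim + off) * 2] = tid  # seed at (0, 0, A)
        fr[0, 0] = 0; fr[0, 1] = 0; fr[0, 2] = 0  # left anchor = seed
        fr[0, 3] = -1; fr[0, 4] = 0; fr[0, 5] = 1; fr[0, 6] = 1
        fr[1, 0] = 0; fr[1, 1] = 0; fr[1, 2] = 0  # right anchor = seed
        fr[1, 3] = 0; fr[1, 4] = -1; fr[1, 5] = 1; fr[1, 6] = 1
        lblock = 0
        rblock = 0
        for k in range(n_steps):
            if lblock > 0 and rblock > 0:
                break  # blocking is absorbing; nothing changes any more
            for i in range(1, -1, -1):  # right front resolves first
                if fr[i, 6] == 0:
                    continue
                j = 1 - i
                tu = fr[i, 3]; tv = fr[i, 4]; ts = fr[i, 5]
                idx = ((tu + off) * dim + (tv + off)) * 2 + ts
                if stamp[idx] == tid:  # target occupied: self-avoidance block
                    fr[i, 6] = 0
                    if i == 0:
                        lblock = k + 1
                    else:
                        rblock = k + 1
                    continue
                stamp[idx] = tid
                ba = _angle_to(tu, tv, ts, fr[i, 0], fr[i, 1])
                orient = lo[t, k] if i == 0 else ro[t, k]
                if orient == 1:
                    fa = (ba + 240) % 360  # clockwise remaining arm
                else:
                    fa = (ba + 120) % 360
                fu, fv, fs = _neighbor_at(tu, tv, ts, fa)
                fr[i, 0] = tu; fr[i, 1] = tv; fr[i, 2] = ts
                fr[i, 3] = fu; fr[i, 4] = fv; fr[i, 5] = fs
                # mutual sticky-end closure: the fresh sticky arm faces the
                # other front's anchor while that front's arm faces back.
                if (
                    fr[j, 6] == 1
                    and fu == fr[j, 0] and fv == fr[j, 1] and fs == fr[j, 2]
                    and fr[j, 3] == tu and fr[j, 4] == tv and fr[j, 5] == ts
                ):
                    fr[i, 6] = 0
                    fr[j, 6] = 0
                    lblock = k + 1
                    rblock = k + 1
        out[t, 0] = lblock
        out[t, 1] = rblock
    return out


def block_steps(left_orients: np.ndarray, right_orients: np.ndarray) -> np.ndarray:
    """Run a batch of growth trials; return per-trial front blocking steps.

    Parameters
    ----------
    left_orients, right_orients:
        Integer arrays of shape ``(n_trials, n_steps)`` with values 1 or 2.

    Returns
    -------
    ``(n_trials, 2)`` int32 array: 1-based step at which the left (column 0)
    and right (column 1) front became blocked, 0 if still active after the
    last step.
    """
    lo = np.ascontiguousarray(left_orients, dtype=np.int8)
    ro = np.ascontiguousarray(right_orients, dtype=np.int8)
    if lo.shape != ro.shape or lo.ndim != 2:
        raise ValueError("orientation arrays must share shape (n_trials, n_steps)")
    if lo.size and (min(lo.min(), ro.min()) < 1 or max(lo.max(), ro.max()) > 2):
        raise ValueError("orientation values must be 1 or 2")
    return _block_steps(lo, ro)
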