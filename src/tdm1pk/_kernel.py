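"""Fast batched concentration kernel for the two-compartment infusion model.

The estimation inner loop evaluates subject-level concentration grids many
thousands of times.  Rather than summing the closed-form solution dose by
dose at every observation (O(doses x times) exponentials), the kernel
propagates the two exponential modes of the disposition model sequentially
through the merged event list of each subject: between events each mode
decays as ``y <- y e^{-lam dt} + c R (1 - e^{-lam dt})`` with ``R`` the
total active infusion rate, which is the exact piecewise-constant-input
solution.  This is algebraically identical to superposition of the
closed-form single-dose solutions in :mod:`tdm1pk.model` but costs
O(doses + times) exponentials per subject.

Compiled with numba when available; a pure-python fallback keeps the
package functional (slowly) without it.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["batch_concentrations", "HAVE_NUMBA"]

_BIG = 1e300


def _conc_batch_py(cl, vc, q, vp, dose_t, rate, end_t, end_rate, obs_t, out):
    n, nd = rate.shape
    nt = obs_t.shape[1]
    for i in range(n):
        k10 = cl[i] / vc[i]
        k12 = q[i] / vc[i]
        k21 = q[i] / vp[i]
        s = k10 + k12 + k21
        disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        al = 0.5 * (s + disc)
        be = max(0.5 * (s - disc), 1e-12)
        a = (al - k21) / max(al - be, 1e-12)
        ca = a / (al * vc[i])
        cb = (1.0 - a) / (be * vc[i])

        ya = 0.0  # alpha-mode concentration component
        yb = 0.0  # beta-mode concentration component
        rtot = 0.0  # active infusion rate (mg/day)
        ia = 0  # next dose start
        ib = 0  # next infusion end
        tcur = _BIG
        if nd > 0:
            tcur = dose_t[i, 0]
        if nt > 0 and obs_t[i, 0] < tcur:
            tcur = obs_t[i, 0]
        for it in range(nt):
            tobs = obs_t[i, it]
            while True:
                # next event among: infusion end, observation, dose start
                te = tobs
                kind = 1  # 0 end, 1 obs, 2 start
                if ib < nd and end_rate[i, ib] > 0.0 and end_t[i, ib] <= te:
                    te = end_t[i, ib]
                    kind = 0
                if ia < nd and rate[i, ia] > 0.0 and dose_t[i, ia] < te:
                    te = dose_t[i, ia]
                    kind = 2
                dt = te - tcur
                if dt > 0.0:
                    ea = math.exp(-al * dt)
                    eb = math.exp(-be * dt)
                    ya = ya * ea + ca * rtot * (1.0 - ea)
                    yb = yb * eb + cb * rtot * (1.0 - eb)
                    tcur = te
                if kind == 0:
                    rtot -= end_rate[i, ib]
                    ib += 1
                elif kind == 2:
                    rtot += rate[i, ia]
                    ia += 1
                else:
                    c = ya + yb
                    out[i, it] = c if c > 1e-10 else 1e-10
                    break
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _conc_batch = njit(cache=True, fastmath=True)(_conc_batch_py)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _conc_batch = _conc_batch_py
    HAVE_NUMBA = False


def batch_concentrations(cl, vc, q, vp, dose_t, rate, end_t, end_rate, obs_t):
    """Concentrations (n, T) for n subjects with padded, time-sorted grids.

    ``rate`` is amount/duration per dose (0 rows are inert padding);
    ``end_t``/``end_rate`` are the infusion end times sorted within each
    subject with their matching rates; ``obs_t`` must be non-decreasing
    per subject.  An observation at exactly a dose-start time precedes the
    dose (pre-dose sample); one at exactly an infusion end sees the full
    infusion.
    """
    out = np.empty_like(obs_t)
    return _conc_batch(cl, vc, q, vp, dose_t, rate, end_t, end_rate, obs_t, out)
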