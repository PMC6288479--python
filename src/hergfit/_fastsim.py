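"""Numba kernel for the gate-factorised fast simulator.

The two Hodgkin–Huxley gates obey scalar linear ODEs

    da/dt = kO(V)·(1 - a) - kC(V)·a,    dr/dt = kA(V)·(1 - r) - kI(V)·r.

At constant voltage the exact update over a step h is
a ← a_inf + (a - a_inf)·exp(-h/tau); on segments where V varies (ramp,
sine) the same update with V frozen at the substep midpoint is the
second-order exponential-midpoint (Magnus) rule.  Hold segments are
therefore integrated *exactly* in one step per sample, ramp/sine segments
with substeps of at most ``dt_smooth`` ms.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .protocol import Hold, Ramp, Sine, VoltageProtocol

_KIND_HOLD = 0
_KIND_RAMP = 1
_KIND_SINE = 2


def protocol_plan(protocol: VoltageProtocol):
    """Compile a protocol into flat arrays consumable by the kernel
    (memoised on the protocol instance)."""
    cached = getattr(protocol, "_fastsim_plan", None)
    if cached is not None:
        return cached
    n = len(protocol.segments)
    kinds = np.empty(n, dtype=np.int64)
    t0 = np.asarray(protocol.boundaries[:-1], dtype=float)
    t1 = np.asarray(protocol.boundaries[1:], dtype=float)
    par = np.zeros((n, 4), dtype=float)
    for i, seg in enumerate(protocol.segments):
        if isinstance(seg, Hold):
            kinds[i] = _KIND_HOLD
            par[i, 0] = seg.v
        elif isinstance(seg, Ramp):
            kinds[i] = _KIND_RAMP
            par[i, 0] = seg.v_start
            par[i, 1] = (seg.v_end - seg.v_start) / seg.duration
        elif isinstance(seg, Sine):
            kinds[i] = _KIND_SINE
            par[i, 0] = seg.v_offset
            par[i, 1] = seg.amplitude
            par[i, 2] = 2.0 * math.pi / seg.period
            par[i, 3] = seg.phase
        else:  # pragma: no cover - protocol validates kinds
            raise TypeError(f"unsupported segment type: {type(seg)!r}")
    plan = (kinds, t0, t1, par)
    protocol._fastsim_plan = plan
    return plan


@njit(cache=True)
def _segment_voltage(kind, p0, p1, p2, p3, t_local):
    if kind == _KIND_HOLD:
        return p0
    elif kind == _KIND_RAMP:
        return p0 + p1 * t_local
    else:
        return p0 + p1 * math.sin(p2 * t_local + p3)


@njit(cache=True)
def propagate_gates(theta, kinds, seg_t0, seg_t1, seg_par, times, dt_smooth, a0, r0):
    """Propagate (a, r) from t = 0, recording gate values at ``times``.

    ``theta`` is the 9-vector (kO1..kA2, GKr); only the kinetics are used.
    Returns (a, r) arrays aligned with ``times``.
    """
    kO1, kO2, kC1, kC2, kI1, kI2, kA1, kA2 = (
        theta[0], theta[1], theta[2], theta[3],
        theta[4], theta[5], theta[6], theta[7],
    )
    n = times.size
    a_out = np.empty(n)
    r_out = np.empty(n)
    a = a0
    r = r0
    t_cur = 0.0
    i = 0
    for s in range(kinds.size):
        kind = kinds[s]
        t_end = seg_t1[s]
        t_start = seg_t0[s]
        p0 = seg_par[s, 0]
        p1 = seg_par[s, 1]
        p2 = seg_par[s, 2]
        p3 = seg_par[s, 3]
        while True:
            # Next target: the next sample if it falls in this segment,
            # otherwise the segment end.
            if i < n and times[i] <= t_end + 1e-9:
                t_target = times[i]
                if t_target > t_end:
                    t_target = t_end
                is_sample = True
            else:
                t_target = t_end
                is_sample = False
            dt_total = t_target - t_cur
            if dt_total > 0.0:
                if kind == _KIND_HOLD:
                    nsub = 1
                else:
                    nsub = int(math.ceil(dt_total / dt_smooth))
                    if nsub < 1:
                        nsub = 1
                h = dt_total / nsub
                for j in range(nsub):
                    tm = t_cur + (j + 0.5) * h
                    v = _segment_voltage(kind, p0, p1, p2, p3, tm - t_start)
                    kO = kO1 * math.exp(kO2 * v)
                    kC = kC1 * math.exp(-kC2 * v)
                    kI = kI1 * math.exp(kI2 * v)
                    kA = kA1 * math.exp(-kA2 * v)
                    sa = kO + kC
                    sr = kA + kI
                    ea = math.exp(-h * sa)
                    er = math.exp(-h * sr)
                    a_inf = kO / sa
                    r_inf = kA / sr
                    a = a_inf + (a - a_inf) * ea
                    r = r_inf + (r - r_inf) * er
                t_cur = t_target
            if is_sample:
                a_out[i] = a
                r_out[i] = r
                i += 1
                if t_cur >= t_end:
                    break
            else:
                break
    # Any trailing samples at the very end (numerical boundary slack).
    while i < n:
        a_out[i] = a
        r_out[i] = r
        i += 1
    return a_out, r_out
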