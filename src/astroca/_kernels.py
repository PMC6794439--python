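"""Numba kernels: float64 Euler twin and the fixed-point digital core.

Both kernels step the system in the same dataflow order:
(1) neuron voltage with threshold/reset, (2) 2-AG with spike increment
applied before the decay update, (3) IP3, (4) Q2 and the h update written
division-free as dh = dt*a2*(Q2*(1-h) - h*Ca), (5) gates, fluxes and Ca.

The fixed-point core works on raw two's-complement integers in the global
Q4.34 format.  Multiplication by a model constant is a signed shift-add
(SCM) plan; the variable*variable products use a full 39x39 multiply with
truncation of the 34 low bits.  All results saturate at the format bounds
and saturation events are counted per step.

Layout of packed designs (see digital.build_designs):

* All SCM plans live in two flat arrays ``plan_signs`` / ``plan_shifts``
  with CSR-style offsets ``plan_start``; a plan is referenced by index.
* Each PWL function is (breakpoint raws, per-segment intercept raws,
  per-segment slope-plan indices), also CSR-packed across the four
  functions in the order q2, m_inf, n_inf, hill2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Q4.34 constants
FRAC_BITS = 34
RAW_ONE = 1 << FRAC_BITS
RAW_MAX = (1 << 38) - 1
RAW_MIN = -(1 << 38)


@njit(cache=True)
def euler_core(n, dt, mode, clamp, spike_steps,
               tau_m, drive, v_th,
               tau_ag, r_ag, ip3_star, tau_ip3, r_ip3,
               a2, d1, d2, d3, d5, c0, c1, r_l, r_c, v_er, k_er,
               v0, ag0, ip30, ca0, h0, out):
    """Forward Euler in float64; records 10 series per step (pre-update)."""
    v = v0
    ag = ag0
    ip3 = ip30
    ca = ca0
    h = h0
    spike_ptr = 0
    for i in range(n):
        if mode == 0:
            ip3 = clamp[i]
        spike = False
        if mode == 1:
            while spike_ptr < spike_steps.size and spike_steps[spike_ptr] == i:
                spike = True
                spike_ptr += 1
        q2 = d2 * (ip3 + d1) / (ip3 + d3)
        m = ip3 / (ip3 + d1)
        nn = ca / (ca + d5)
        m3 = m * m * m
        n3 = nn * nn * nn
        h3 = h * h * h
        drv = c0 - (1.0 + c1) * ca
        jc = r_c * m3 * n3 * h3 * drv
        jl = r_l * drv
        jp = v_er * ca * ca / (k_er * k_er + ca * ca)

        out[0, i] = v
        out[1, i] = ag
        out[2, i] = ip3
        out[3, i] = ca
        out[4, i] = h
        out[5, i] = m3
        out[6, i] = n3
        out[7, i] = jp
        out[8, i] = jc
        out[9, i] = jl

        if mode == 1:
            # (1) neuron (idle in clamp mode, matching the reference)
            v = v + dt / tau_m * (-v + drive)
            if v >= v_th:
                v = 0.0
            # (2) 2-AG: spike increment, then decay on the incremented value
            if spike:
                ag = ag + r_ag
            ag = ag + dt * (-ag / tau_ag)
            # (3) IP3
            ip3 = ip3 + dt * ((ip3_star - ip3) / tau_ip3 + r_ip3 * ag)
        # (4) h, division-free form
        h = h + dt * a2 * (q2 * (1.0 - h) - h * ca)
        # (5) Ca
        ca = ca + dt * (jc + jl - jp)
    return 0


# ---------------------------------------------------------------------------
# fixed-point helpers


@njit(cache=True, inline="always")
def _sat(x, counter):
    if x > RAW_MAX:
        counter[0] += 1
        return RAW_MAX
    if x < RAW_MIN:
        counter[0] += 1
        return RAW_MIN
    return x


@njit(cache=True, inline="always")
def _scm(x, pid, plan_signs, plan_shifts, plan_start, counter):
    """Apply SCM plan ``pid`` to raw value x: sum of sign*(x >> shift)."""
    acc = np.int64(0)
    for k in range(plan_start[pid], plan_start[pid + 1]):
        acc += plan_signs[k] * (x >> plan_shifts[k])
    return _sat(acc, counter)


@njit(cache=True, inline="always")
def _mul(a, b, counter):
    """floor(a*b / 2^34) via a 17/17 split of ``a`` (int64-overflow safe)."""
    ah = a >> 17
    al = a & 0x1FFFF
    r = (ah * b + ((al * b) >> 17)) >> 17
    return _sat(r, counter)


@njit(cache=True, inline="always")
def _pwl(x, f, pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start, pwl_seg_start,
         plan_signs, plan_shifts, plan_start, counter):
    """Evaluate packed PWL function ``f`` at raw x (clamped to its domain)."""
    b0 = pwl_bp_start[f]
    b1 = pwl_bp_start[f + 1]
    if x <= pwl_bp[b0]:
        x = pwl_bp[b0]
    elif x >= pwl_bp[b1 - 1]:
        x = pwl_bp[b1 - 1]
    lo = b0
    hi = b1 - 1
    while hi - lo > 1:            # binary search: segment lo..lo+1
        mid = (lo + hi) >> 1
        if pwl_bp[mid] <= x:
            lo = mid
        else:
            hi = mid
    seg = pwl_seg_start[f] + (lo - b0)
    y = pwl_intercept[seg] + _scm(x, pwl_plan[seg], plan_signs, plan_shifts,
                                  plan_start, counter)
    return _sat(y, counter)


# constant-plan indices (order fixed by digital.build_designs)
P_DT = 0
P_INV_TAU_M = 1
P_INV_TAU_AG = 2
P_INV_TAU_IP3 = 3
P_R_IP3 = 4
P_A2 = 5
P_R_C = 6
P_ONE_PLUS_C1 = 7
P_V_ER = 8
N_CONST_PLANS = 9

# packed PWL function indices
F_Q2 = 0
F_M_INF = 1
F_N_INF = 2
F_HILL2 = 3


@njit(cache=True)
def digital_core(n, mode, clamp_raw, spike_steps,
                 plan_signs, plan_shifts, plan_start,
                 pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start, pwl_seg_start,
                 rm_isyn_raw, v_th_raw, ip3_star_raw, r_ag_raw, c0_raw,
                 r_l_raw, one_raw,
                 v0, ag0, ip30, ca0, h0,
                 out, sat_out):
    """Fixed-point Euler emulation; writes 10 raw series + saturation counts.

    out rows: V, AG, IP3, Ca, h, m_inf3, n_inf3, J_pump, J_chan, J_leak
    (flux rows are instantaneous fluxes in uM/s, before the dt scaling).
    """
    counter = np.zeros(1, np.int64)
    v = v0
    ag = ag0
    ip3 = ip30
    ca = ca0
    h = h0
    spike_ptr = 0
    for i in range(n):
        if mode == 0:
            ip3 = clamp_raw[i]
        spike = False
        if mode == 1:
            while spike_ptr < spike_steps.size and spike_steps[spike_ptr] == i:
                spike = True
                spike_ptr += 1
        sat_before = counter[0]

        # gates and fluxes from the current state
        q2 = _pwl(ip3, F_Q2, pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start,
                  pwl_seg_start, plan_signs, plan_shifts, plan_start, counter)
        m = _pwl(ip3, F_M_INF, pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start,
                 pwl_seg_start, plan_signs, plan_shifts, plan_start, counter)
        nn = _pwl(ca, F_N_INF, pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start,
                  pwl_seg_start, plan_signs, plan_shifts, plan_start, counter)
        pp = _pwl(ca, F_HILL2, pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start,
                  pwl_seg_start, plan_signs, plan_shifts, plan_start, counter)
        m3 = _mul(_mul(m, m, counter), m, counter)
        n3 = _mul(_mul(nn, nn, counter), nn, counter)
        h3 = _mul(_mul(h, h, counter), h, counter)
        g = _mul(_mul(m3, n3, counter), h3, counter)
        drv = _sat(c0_raw - _scm(ca, P_ONE_PLUS_C1, plan_signs, plan_shifts,
                                 plan_start, counter), counter)
        jc = _mul(_scm(g, P_R_C, plan_signs, plan_shifts, plan_start, counter),
                  drv, counter)
        jl = _mul(r_l_raw, drv, counter)
        jp = _scm(pp, P_V_ER, plan_signs, plan_shifts, plan_start, counter)

        out[0, i] = v
        out[1, i] = ag
        out[2, i] = ip3
        out[3, i] = ca
        out[4, i] = h
        out[5, i] = m3
        out[6, i] = n3
        out[7, i] = jp
        out[8, i] = jc
        out[9, i] = jl

        if mode == 1:
            # (1) neuron: V += (1/tau_m) * dt * (Rm*Isyn - V); dt is applied
            # first so the 1/tau_m = 10 gain never overflows the +-16 range
            u = _sat(rm_isyn_raw - v, counter)
            v = _sat(v + _scm(_scm(u, P_DT, plan_signs, plan_shifts,
                                   plan_start, counter),
                              P_INV_TAU_M, plan_signs, plan_shifts, plan_start,
                              counter),
                     counter)
            if v >= v_th_raw:
                v = 0
            # (2) 2-AG
            if spike:
                ag = _sat(ag + r_ag_raw, counter)
            dec = _scm(_scm(-ag, P_INV_TAU_AG, plan_signs, plan_shifts,
                            plan_start, counter),
                       P_DT, plan_signs, plan_shifts, plan_start, counter)
            ag = _sat(ag + dec, counter)
            # (3) IP3 += dt * ((IP3* - IP3)/tau_ip3 + r_ip3 * AG)
            s1 = _scm(_sat(ip3_star_raw - ip3, counter), P_INV_TAU_IP3,
                      plan_signs, plan_shifts, plan_start, counter)
            s2 = _scm(ag, P_R_IP3, plan_signs, plan_shifts, plan_start, counter)
            ip3 = _sat(ip3 + _scm(_sat(s1 + s2, counter), P_DT, plan_signs,
                                  plan_shifts, plan_start, counter), counter)

        # (4) h += dt * a2 * (Q2*(1-h) - h*Ca)
        u1 = _mul(q2, _sat(one_raw - h, counter), counter)
        u2 = _mul(h, ca, counter)
        dh = _scm(_scm(_sat(u1 - u2, counter), P_A2, plan_signs, plan_shifts,
                       plan_start, counter),
                  P_DT, plan_signs, plan_shifts, plan_start, counter)
        h = _sat(h + dh, counter)

        # (5) Ca += dt * (J_chan + J_leak - J_pump)
        net = _sat(_sat(jc + jl, counter) - jp, counter)
        ca = _sat(ca + _scm(net, P_DT, plan_signs, plan_shifts, plan_start,
                            counter), counter)

        sat_out[i] = counter[0] - sat_before
    return counter[0]
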