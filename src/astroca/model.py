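"""Double-precision reference model of the neuron-astrocyte cascade.

The cascade couples four mechanisms:

1. A leaky integrate-and-fire neuron, ``tau_m dV/dt = -V + R_m I_syn``,
   spiking at ``V_th`` and resetting to 0.
2. Endocannabinoid release: each delivered spike adds ``r_AG`` to the
   2-AG pool, which decays with time constant ``tau_AG``.
3. IP3 production: ``dIP3/dt = (IP3* - IP3)/tau_ip3 + r_ip3 * AG``.
4. Li-Rinzel / De Pitta calcium dynamics:

   .. math::

        dCa/dt &= J_{chan} + J_{leak} - J_{pump} \\
        dh/dt  &= (h_\\infty - h)/\\tau_h

   with CICR channel flux
   ``J_chan = r_C m_inf^3 n_inf^3 h^3 (c0 - (1+c1) Ca)``, leak
   ``J_leak = r_L (c0 - (1+c1) Ca)`` and SERCA pump
   ``J_pump = v_ER Ca^2/(k_ER^2 + Ca^2)``.  The gating steady states are
   ``m_inf = IP3/(IP3+d1)``, ``n_inf = Ca/(Ca+d5)``,
   ``h_inf = Q2/(Q2+Ca)`` with ``Q2 = d2 (IP3+d1)/(IP3+d3)`` and
   ``tau_h = 1/(a2 (Q2 + Ca))``.

Under an IP3 clamp protocol mechanisms 1-3 are bypassed and the clamp
waveform is substituted for IP3.

The reference integrator is adaptive Runge-Kutta (``scipy.solve_ivp``)
restarted at every discontinuity (spike delivery or clamp edge); spikes
are realized as instantaneous additions of ``r_AG`` to the 2-AG pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, SolverError, ValidationError
from .params import AstroParams, InitialState, NeuronParams
from .protocols import Protocol
from .trace import Trace

__all__ = [
    "SystemState",
    "compute_q2",
    "gating_steady_states",
    "compute_fluxes",
    "astro_derivatives",
    "neuron_step",
    "simulate_reference",
    "simulate_euler_reference",
]


@dataclass
class SystemState:
    """Instantaneous state of the coupled system."""

    t: float = 0.0
    V: float = 0.0
    AG: float = 0.0
    IP3: float = 0.16
    Ca: float = 0.071006
    h: float = 0.7791


# ---------------------------------------------------------------------------
# pointwise model functions (vectorized over numpy arrays)


def compute_q2(ip3, p: AstroParams):
    """Effective Ca2+ dissociation constant of IP3R inactivation,
    ``Q2 = d2 (IP3 + d1) / (IP3 + d3)``.

    Monotone increasing in IP3 (for ``d3 > d1``) from ``d2 d1/d3`` at zero
    IP3 towards the asymptote ``d2``.
    """
    ip3 = np.asarray(ip3, float)
    if np.any(ip3 < 0):
        raise DomainError("IP3 concentration must be non-negative")
    out = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    return out if out.ndim else float(out)


def gating_steady_states(ip3, ca, p: AstroParams):
    """Steady-state IP3R gates and the h time constant.

    Returns ``(m_inf, n_inf, h_inf, tau_h)`` where ``m_inf`` is the
    IP3-induced (IICR) gate, ``n_inf`` the Ca2+-induced (CICR) gate,
    ``h_inf`` the slow-inactivation steady state and ``tau_h`` its time
    constant in seconds.
    """
    ip3 = np.asarray(ip3, float)
    ca = np.asarray(ca, float)
    if np.any(ip3 < 0) or np.any(ca < 0):
        raise DomainError("concentrations must be non-negative")
    q2 = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    h_inf = q2 / (q2 + ca)
    tau_h = 1.0 / (p.a2 * (q2 + ca))
    if m_inf.ndim:
        return m_inf, n_inf, h_inf, tau_h
    return float(m_inf), float(n_inf), float(h_inf), float(tau_h)


def compute_fluxes(ca, h, ip3, p: AstroParams):
    """ER<->cytosol calcium fluxes ``(J_chan, J_leak, J_pump)`` in uM/s."""
    ca = np.asarray(ca, float)
    h = np.asarray(h, float)
    ip3 = np.asarray(ip3, float)
    if np.any(ca < 0) or np.any(ip3 < 0) or np.any(h < 0) or np.any(h > 1):
        raise DomainError("inputs must satisfy ca, ip3 >= 0 and 0 <= h <= 1")
    m_inf = ip3 / (ip3 + p.d1)
    n_inf = ca / (ca + p.d5)
    drive = p.c0 - (1.0 + p.c1) * ca
    j_chan = p.r_C * (m_inf * n_inf * h) ** 3 * drive
    j_leak = p.r_L * drive
    j_pump = p.v_ER * ca * ca / (p.k_ER ** 2 + ca * ca)
    if j_chan.ndim:
        return j_chan, j_leak, j_pump
    return float(j_chan), float(j_leak), float(j_pump)


def astro_derivatives(s: SystemState, p: AstroParams, ag_input_rate: float = 0.0):
    """Smooth part of the astrocyte vector field, ``d(AG, IP3, Ca, h)/dt``.

    Spike impulses are not part of the smooth field: the integrator adds
    ``r_AG`` to the 2-AG pool at each delivery time.  ``ag_input_rate``
    admits an optional continuous 2-AG source (uM/s).
    """
    j_chan, j_leak, j_pump = compute_fluxes(s.Ca, s.h, s.IP3, p)
    q2 = compute_q2(s.IP3, p)
    h_inf = q2 / (q2 + s.Ca)
    d_ag = -s.AG / p.tau_AG + ag_input_rate
    d_ip3 = (p.IP3_star - s.IP3) / p.tau_ip3 + p.r_ip3 * s.AG
    d_ca = j_chan + j_leak - j_pump
    d_h = (h_inf - s.h) * p.a2 * (q2 + s.Ca)
    return d_ag, d_ip3, d_ca, d_h


def neuron_step(V: float, p: NeuronParams, dt: float) -> tuple[float, bool]:
    """One forward-Euler step of the IF neuron with threshold/reset."""
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if dt >= p.tau_m:
        warnings.warn("dt >= tau_m: Euler step of the IF neuron is unstable",
                      stacklevel=2)
    if V >= p.V_th:
        return p.V_reset, True
    v_next = V + dt / p.tau_m * (-V + p.drive)
    if v_next >= p.V_th:
        return p.V_reset, True
    return v_next, False


# ---------------------------------------------------------------------------
# reference integration


def _rhs_clamp(t, y, ip3, p: AstroParams):
    ca, h = y
    q2 = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    m = ip3 / (ip3 + p.d1)
    n = ca / (ca + p.d5)
    drive = p.c0 - (1.0 + p.c1) * ca
    d_ca = (p.r_C * (m * n * h) ** 3 + p.r_L) * drive \
        - p.v_ER * ca * ca / (p.k_ER ** 2 + ca * ca)
    d_h = (q2 / (q2 + ca) - h) * p.a2 * (q2 + ca)
    return (d_ca, d_h)


def _rhs_spike(t, y, p: AstroParams):
    ag, ip3, ca, h = y
    q2 = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    m = ip3 / (ip3 + p.d1)
    n = ca / (ca + p.d5)
    drive = p.c0 - (1.0 + p.c1) * ca
    d_ca = (p.r_C * (m * n * h) ** 3 + p.r_L) * drive \
        - p.v_ER * ca * ca / (p.k_ER ** 2 + ca * ca)
    d_h = (q2 / (q2 + ca) - h) * p.a2 * (q2 + ca)
    d_ag = -ag / p.tau_AG
    d_ip3 = (p.IP3_star - ip3) / p.tau_ip3 + p.r_ip3 * ag
    return (d_ag, d_ip3, d_ca, d_h)


def _integrate_piecewise(rhs, y0, breakpoints, t_grid, jumps, rtol, atol, max_step):
    """Integrate ``rhs`` over consecutive intervals of ``breakpoints``,
    applying the state ``jumps[i]`` at the start of interval i, and sample
    the solution on ``t_grid``.  Returns an array (len(t_grid), len(y0))."""
    y = np.asarray(y0, float).copy()
    out = np.empty((len(t_grid), len(y)))
    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if jumps[i] is not None:
            y = y + jumps[i]
        if t1 <= t0:
            continue
        sel = (t_grid >= t0) & (t_grid < t1)
        args = rhs[1][i] if isinstance(rhs[1], list) else rhs[1]
        sol = solve_ivp(rhs[0], (t0, t1), y, args=args, rtol=rtol, atol=atol,
                        max_step=max_step, dense_output=True)
        if not sol.success:
            raise SolverError(f"reference integrator failed near t={sol.t[-1]:.6g} s: "
                              f"{sol.message}")
        if sel.any():
            out[sel] = sol.sol(t_grid[sel]).T
        y = sol.y[:, -1]
    return out


def simulate_reference(proto: Protocol,
                       neuron: NeuronParams | None = None,
                       astro: AstroParams | None = None,
                       dt_out: float = 1e-3,
                       initial: InitialState | None = None,
                       rtol: float = 1e-8,
                       atol: float = 1e-10,
                       max_step: float = 1.0) -> Trace:
    """Integrate the reference model under a protocol and sample uniformly.

    In clamp mode only (Ca, h) are integrated and the IP3 series is the
    clamp waveform; in spike modes the full (AG, IP3, Ca, h) chain runs
    with the neuron voltage reconstructed from its closed-form solution.
    Derived flux and gating series are evaluated from the sampled states.
    """
    neuron = neuron or NeuronParams()
    astro = astro or AstroParams()
    init = initial or InitialState()
    if dt_out <= 0:
        raise ValidationError("dt_out must be positive")
    n = int(round(proto.T_total / dt_out))
    t = dt_out * np.arange(n)

    if n == 0:
        empty = np.empty(0)
        return Trace(t=empty, V=empty, AG=empty, IP3=empty, Ca=empty, h=empty,
                     J_chan=empty, J_leak=empty, J_pump=empty,
                     m_inf3=empty, n_inf3=empty, dt=dt_out,
                     meta={"protocol": proto.kind})

    if proto.kind == "ip3_clamp":
        edges = proto.edges
        args = [(lvl, astro) for lvl in proto.levels]
        y = _integrate_piecewise((_rhs_clamp, args), (init.Ca, init.h), edges, t,
                                 [None] * len(proto.levels), rtol, atol, max_step)
        ca, h = y[:, 0], y[:, 1]
        ip3 = proto.ip3_at(t)
        ag = np.zeros(n)
        v = np.zeros(n)
    else:
        times = np.asarray(proto.spike_times, float)
        breakpoints = np.concatenate([[0.0], times, [proto.T_total]])
        jumps = [None] + [np.array([astro.r_AG, 0.0, 0.0, 0.0])] * len(times)
        y0 = (init.AG, init.IP3, init.Ca, init.h)
        y = _integrate_piecewise((_rhs_spike, (astro,)), y0, breakpoints, t,
                                 jumps, rtol, atol, max_step)
        ag, ip3, ca, h = y.T
        isi = neuron.isi()
        if np.isfinite(isi):
            phase = np.mod(t, isi)
            v = neuron.drive * (1.0 - np.exp(-phase / neuron.tau_m))
        else:
            v = neuron.drive * (1.0 - np.exp(-t / neuron.tau_m))

    m_inf, n_inf, _, _ = gating_steady_states(ip3, np.maximum(ca, 0.0), astro)
    j_chan, j_leak, j_pump = compute_fluxes(np.maximum(ca, 0.0),
                                            np.clip(h, 0.0, 1.0), ip3, astro)
    meta = {"protocol": proto.kind,
            "neuron": {f: getattr(neuron, f) for f in neuron.__dataclass_fields__},
            "astro": {f: getattr(astro, f) for f in astro.__dataclass_fields__},
            "engine": "reference", "rtol": rtol, "dt_out": dt_out}
    return Trace(t=t, V=v, AG=ag, IP3=ip3, Ca=ca, h=h,
                 J_chan=j_chan, J_leak=j_leak, J_pump=j_pump,
                 m_inf3=m_inf ** 3, n_inf3=n_inf ** 3, dt=dt_out, meta=meta)


def simulate_euler_reference(proto: Protocol,
                             neuron: NeuronParams | None = None,
                             astro: AstroParams | None = None,
                             dt: float = 1e-3,
                             initial: InitialState | None = None) -> Trace:
    """Double-precision forward-Euler integration in the digital update order.

    This is the floating-point twin of the fixed-point emulator: identical
    stepping and spike handling, but exact real arithmetic and exact
    nonlinear functions.  It serves as the oracle separating time-
    discretization error from quantization/approximation error.
    """
    from ._kernels import euler_core

    neuron = neuron or NeuronParams()
    astro = astro or AstroParams()
    init = initial or InitialState()
    n = int(round(proto.T_total / dt))
    t = dt * np.arange(n)
    if proto.kind == "ip3_clamp":
        clamp = proto.ip3_at(t) if n else np.empty(0)
        spikes = np.zeros(0, np.int64)
        mode = 0
    else:
        clamp = np.empty(0)
        spikes = np.minimum((np.asarray(proto.spike_times) / dt).astype(np.int64), n - 1)
        mode = 1
    p = astro
    out = np.empty((10, n))
    euler_core(n, dt, mode, clamp, spikes,
               neuron.tau_m, neuron.drive, neuron.V_th,
               p.tau_AG, p.r_AG, p.IP3_star, p.tau_ip3, p.r_ip3,
               p.a2, p.d1, p.d2, p.d3, p.d5, p.c0, p.c1, p.r_L, p.r_C,
               p.v_ER, p.k_ER,
               init.V, init.AG, init.IP3, init.Ca, init.h, out)
    v, ag, ip3, ca, h, m3, n3, jp, jc, jl = out
    meta = {"protocol": proto.kind, "engine": "euler", "dt": dt}
    return Trace(t=t, V=v, AG=ag, IP3=ip3, Ca=ca, h=h,
                 J_chan=jc, J_leak=jl, J_pump=jp, m_inf3=m3, n_inf3=n3,
                 dt=dt, meta=meta)
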