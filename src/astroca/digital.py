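"""Bit-accurate emulation of the fixed-point astrocyte/neuron circuit.

The circuit advances the five state registers by forward Euler in Q4.34
arithmetic.  Its datapath uses three kinds of operation only:

* 39-bit saturating adders/subtractors;
* SCM shift-add plans for every multiplication by a model constant
  (including the per-segment slopes of the PWL function tables);
* full 39x39 multipliers with low-bit truncation for the handful of
  variable*variable products (the gate cubes and flux products).

Four scalar nonlinearities are tabulated as PWL functions of one input:
``Q2(IP3)``, ``m_inf(IP3)``, ``n_inf(Ca)`` and the unit SERCA Hill curve
``Ca^2/(k_ER^2+Ca^2)``.  The cubes ``m_inf^3``/``n_inf^3``/``h^3`` are
then formed by two multiplies each, and the h equation is evaluated in
the division-free form ``dh = dt a2 (Q2 (1-h) - h Ca)`` which is exact
(no PWL needed for ``h_inf`` or ``1/tau_h``).

Rate constants are applied as a per-constant SCM plan composed with one
shared plan for dt, so that every state equation advances on the same
realized time step (the residual dt error is a pure common clock skew
rather than a per-equation rate distortion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .fixed import Q4_34, FixedValue, fx_add, fx_mul, fx_scm_mul, fx_sub, quantize
from .params import AstroParams, InitialState, NeuronParams
from .protocols import Protocol
from .pwl import PwlFunction, build_pwl_to_tol
from .scm import ScmPlan, scm_decompose
from .trace import Trace

__all__ = ["DesignSet", "DigitalState", "build_designs", "step_digital",
           "run_digital"]

#: order of the constant SCM plans in the packed plan table
_CONST_PLAN_ORDER = ("dt", "inv_tau_m", "inv_tau_ag", "inv_tau_ip3",
                     "r_ip3", "a2", "r_c", "one_plus_c1", "v_er")
#: order of the packed PWL functions
_PWL_ORDER = ("q2", "m_inf", "n_inf", "j_pump_hill")

#: default per-function PWL error budgets (input units -> output units).
#: Sized so the end-to-end digital-vs-reference calcium error stays well
#: inside the validated envelope; config-exposed through build_designs.
DEFAULT_PWL_TOL = 2e-4


@dataclass
class DigitalState:
    """Raw Q4.34 registers of the emulated circuit."""

    V: FixedValue
    AG: FixedValue
    IP3: FixedValue
    Ca: FixedValue
    h: FixedValue
    # registered intermediates of the last step
    m_inf3: FixedValue = field(default_factory=lambda: FixedValue(0))
    n_inf3: FixedValue = field(default_factory=lambda: FixedValue(0))
    J_pump: FixedValue = field(default_factory=lambda: FixedValue(0))
    J_chan: FixedValue = field(default_factory=lambda: FixedValue(0))
    J_leak: FixedValue = field(default_factory=lambda: FixedValue(0))
    Q2: FixedValue = field(default_factory=lambda: FixedValue(0))
    h3: FixedValue = field(default_factory=lambda: FixedValue(0))


@dataclass
class DesignSet:
    """Complete digital design: PWL tables, SCM plans and quantized constants."""

    dt: float
    pwl: dict[str, PwlFunction]
    pwl_slope_plans: dict[str, list[ScmPlan]]
    const_plans: dict[str, ScmPlan]
    consts: dict[str, float]          # additive/compare constants (real values)
    neuron: NeuronParams
    astro: AstroParams
    max_terms: int
    max_shift: int

    def const_raw(self, name: str) -> int:
        return quantize(self.consts[name]).raw

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "max_terms": self.max_terms,
            "max_shift": self.max_shift,
            "pwl": {k: v.to_dict() for k, v in self.pwl.items()},
            "pwl_slope_plans": {k: [p.to_dict() for p in v]
                                for k, v in self.pwl_slope_plans.items()},
            "const_plans": {k: v.to_dict() for k, v in self.const_plans.items()},
            "consts": dict(self.consts),
        }

    def to_json(self, path: str | Path | None = None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            Path(path).write_text(s)
        return s

    # -- packing for the numba core -----------------------------------
    def packed(self):
        """Flatten all SCM plans and PWL tables into CSR-style arrays."""
        plans: list[ScmPlan] = [self.const_plans[k] for k in _CONST_PLAN_ORDER]
        pwl_bp, pwl_intercept, pwl_plan = [], [], []
        pwl_bp_start, pwl_seg_start = [0], [0]
        for fname in _PWL_ORDER:
            pf = self.pwl[fname]
            bp_raw = [quantize(float(x)).raw for x in pf.breakpoints]
            nv_raw = [quantize(float(v)).raw for v in pf.node_values]
            for k, plan in enumerate(self.pwl_slope_plans[fname]):
                # intercept chosen so the segment reproduces its left node
                # exactly under the realized (SCM) slope
                pwl_intercept.append(nv_raw[k] - plan.apply_raw(bp_raw[k]))
                pwl_plan.append(len(plans))
                plans.append(plan)
            pwl_bp.extend(bp_raw)
            pwl_bp_start.append(len(pwl_bp))
            pwl_seg_start.append(len(pwl_intercept))
        signs, shifts, start = [], [], [0]
        for plan in plans:
            for s, k in plan.terms:
                signs.append(s)
                shifts.append(k)
            start.append(len(signs))
        i64 = np.int64
        return (np.asarray(signs, i64), np.asarray(shifts, i64),
                np.asarray(start, i64), np.asarray(pwl_bp, i64),
                np.asarray(pwl_intercept, i64), np.asarray(pwl_plan, i64),
                np.asarray(pwl_bp_start, i64), np.asarray(pwl_seg_start, i64))


def build_designs(neuron: NeuronParams | None = None,
                  astro: AstroParams | None = None,
                  dt: float = 1e-3,
                  pwl_tol: float | dict[str, float] = DEFAULT_PWL_TOL,
                  max_segments: int = 256,
                  max_terms: int = 26,
                  max_shift: int = 19) -> DesignSet:
    """Build the PWL tables and SCM plans for one parameter set.

    ``pwl_tol`` is the certified max-abs-error budget per tabulated
    function (a scalar or a per-function mapping); the PWL input domains
    are the physiological ranges IP3 in [0, 2] uM and Ca in
    [0, c0/(1+c1)] uM.
    """
    neuron = neuron or NeuronParams()
    astro = astro or AstroParams()
    if dt <= 0:
        raise ValidationError("dt must be positive")
    p = astro
    tols = ({k: float(pwl_tol) for k in _PWL_ORDER} if np.isscalar(pwl_tol)
            else {**{k: DEFAULT_PWL_TOL for k in _PWL_ORDER}, **pwl_tol})
    ca_hi = p.ca_max
    funcs = {
        "q2": (lambda x: p.d2 * (x + p.d1) / (x + p.d3), (0.0, 2.0)),
        "m_inf": (lambda x: x / (x + p.d1), (0.0, 2.0)),
        "n_inf": (lambda x: x / (x + p.d5), (0.0, ca_hi)),
        "j_pump_hill": (lambda x: x * x / (p.k_ER ** 2 + x * x), (0.0, ca_hi)),
    }
    pwl = {}
    slope_plans = {}
    for name, (f, dom) in funcs.items():
        pf = build_pwl_to_tol(f, dom, tols[name], max_segments=max_segments,
                              name=name)
        pwl[name] = pf
        slope_plans[name] = [scm_decompose(float(s), max_terms, max_shift)
                             for s in pf.slopes]
    const_plans = {
        "dt": scm_decompose(dt, max_terms, max_shift),
        "inv_tau_m": scm_decompose(1.0 / neuron.tau_m, max_terms, max_shift),
        "inv_tau_ag": scm_decompose(1.0 / p.tau_AG, max_terms, max_shift),
        "inv_tau_ip3": scm_decompose(1.0 / p.tau_ip3, max_terms, max_shift),
        "r_ip3": scm_decompose(p.r_ip3, max_terms, max_shift),
        "a2": scm_decompose(p.a2, max_terms, max_shift),
        "r_c": scm_decompose(p.r_C, max_terms, max_shift),
        "one_plus_c1": scm_decompose(1.0 + p.c1, max_terms, max_shift),
        "v_er": scm_decompose(p.v_ER, max_terms, max_shift),
    }
    consts = {"rm_isyn": neuron.drive, "v_th": neuron.V_th,
              "ip3_star": p.IP3_star, "r_ag": p.r_AG, "c0": p.c0,
              "r_l": p.r_L, "one": 1.0}
    return DesignSet(dt=dt, pwl=pwl, pwl_slope_plans=slope_plans,
                     const_plans=const_plans, consts=consts,
                     neuron=neuron, astro=astro,
                     max_terms=max_terms, max_shift=max_shift)


# ---------------------------------------------------------------------------
# pure-Python single step (bit-identical to the numba core; used in tests)


def _pwl_eval_raw(designs: DesignSet, fname: str, x_raw: int,
                  events: list | None = None) -> int:
    pf = designs.pwl[fname]
    bp_raw = [quantize(float(b)).raw for b in pf.breakpoints]
    nv_raw = [quantize(float(v)).raw for v in pf.node_values]
    x = min(max(x_raw, bp_raw[0]), bp_raw[-1])
    seg = 0
    for k in range(len(bp_raw) - 1):
        if bp_raw[k] <= x:
            seg = k
    plan = designs.pwl_slope_plans[fname][seg]
    intercept = nv_raw[seg] - plan.apply_raw(bp_raw[seg])
    fv = FixedValue(x)
    return fx_add(FixedValue(max(min(intercept, Q4_34.raw_max), Q4_34.raw_min)),
                  fx_scm_mul(fv, plan, events), events).raw


def step_digital(state: DigitalState, designs: DesignSet,
                 ip3_clamp: FixedValue | None = None,
                 spike: bool = False,
                 events: list | None = None) -> DigitalState:
    """One Euler step of the digital circuit (reference implementation).

    ``ip3_clamp`` switches the step to clamp mode (AG/IP3 bypassed);
    otherwise ``spike`` marks a 2-AG delivery in this step.  Saturation
    events are appended to ``events`` if given.
    """
    d = designs
    cp = d.const_plans
    sp = lambda v, name: fx_scm_mul(v, cp[name], events)
    q = lambda name: quantize(d.consts[name])

    ip3 = ip3_clamp if ip3_clamp is not None else state.IP3
    v, ag, ca, h = state.V, state.AG, state.Ca, state.h

    q2 = FixedValue(_pwl_eval_raw(d, "q2", ip3.raw, events))
    m = FixedValue(_pwl_eval_raw(d, "m_inf", ip3.raw, events))
    nn = FixedValue(_pwl_eval_raw(d, "n_inf", ca.raw, events))
    pp = FixedValue(_pwl_eval_raw(d, "j_pump_hill", ca.raw, events))
    m3 = fx_mul(fx_mul(m, m, events), m, events)
    n3 = fx_mul(fx_mul(nn, nn, events), nn, events)
    h3 = fx_mul(fx_mul(h, h, events), h, events)
    g = fx_mul(fx_mul(m3, n3, events), h3, events)
    drv = fx_sub(q("c0"), sp(ca, "one_plus_c1"), events)
    j_chan = fx_mul(sp(g, "r_c"), drv, events)
    j_leak = fx_mul(q("r_l"), drv, events)
    j_pump = sp(pp, "v_er")

    if ip3_clamp is None:
        # (1) neuron; dt first so the 1/tau_m = 10 gain cannot overflow
        u = fx_sub(q("rm_isyn"), v, events)
        v_next = fx_add(v, sp(sp(u, "dt"), "inv_tau_m"), events)
        if v_next.raw >= quantize(d.consts["v_th"]).raw:
            v_next = FixedValue(0)
        # (2) 2-AG
        if spike:
            ag = fx_add(ag, q("r_ag"), events)
        dec = sp(sp(FixedValue(-ag.raw), "inv_tau_ag"), "dt")
        ag_next = fx_add(ag, dec, events)
        # (3) IP3; the production term reads the already-updated AG register
        s1 = sp(fx_sub(q("ip3_star"), ip3, events), "inv_tau_ip3")
        s2 = sp(ag_next, "r_ip3")
        ip3_next = fx_add(ip3, sp(fx_add(s1, s2, events), "dt"), events)
    else:
        v_next, ag_next, ip3_next = v, ag, ip3

    # (4) h
    u1 = fx_mul(q2, fx_sub(q("one"), h, events), events)
    u2 = fx_mul(h, ca, events)
    dh = sp(sp(fx_sub(u1, u2, events), "a2"), "dt")
    h_next = fx_add(h, dh, events)

    # (5) Ca
    net = fx_sub(fx_add(j_chan, j_leak, events), j_pump, events)
    ca_next = fx_add(ca, sp(net, "dt"), events)

    return DigitalState(V=v_next, AG=ag_next, IP3=ip3_next, Ca=ca_next,
                        h=h_next, m_inf3=m3, n_inf3=n3, J_pump=j_pump,
                        J_chan=j_chan, J_leak=j_leak, Q2=q2, h3=h3)


def run_digital(proto: Protocol,
                designs: DesignSet,
                initial: InitialState | None = None,
                return_raw: bool = False) -> Trace:
    """Run the emulator over a protocol; returns a dequantized Trace.

    The trace carries a per-sample ``saturations`` series and, in the
    meta, the total saturation count; more than 1% of steps saturating is
    flagged with a prominent warning string in the meta as well.  With
    ``return_raw`` the raw int64 register streams are attached to
    ``meta["raw"]`` for bit-exact regression comparisons.
    """
    from ._kernels import digital_core

    init = initial or InitialState()
    d = designs
    dt = d.dt
    n = int(round(proto.T_total / dt))
    t = dt * np.arange(n)
    if proto.kind == "ip3_clamp":
        mode = 0
        clamp_raw = (np.asarray([quantize(float(l)).raw for l in proto.levels], np.int64)
                     [np.clip(np.searchsorted(proto.edges, t, side="right") - 1,
                              0, max(len(proto.levels) - 1, 0))]
                     if n else np.zeros(0, np.int64))
        spikes = np.zeros(0, np.int64)
    else:
        mode = 1
        clamp_raw = np.zeros(0, np.int64)
        spikes = np.minimum((np.asarray(proto.spike_times) / dt).astype(np.int64),
                            max(n - 1, 0))

    (signs, shifts, start, pwl_bp, pwl_intercept, pwl_plan,
     pwl_bp_start, pwl_seg_start) = d.packed()
    out = np.empty((10, n), np.int64)
    sat = np.zeros(n, np.int64)
    total_sat = 0
    if n:
        total_sat = digital_core(
            n, mode, clamp_raw, spikes,
            signs, shifts, start,
            pwl_bp, pwl_intercept, pwl_plan, pwl_bp_start, pwl_seg_start,
            np.int64(d.const_raw("rm_isyn")), np.int64(d.const_raw("v_th")),
            np.int64(d.const_raw("ip3_star")), np.int64(d.const_raw("r_ag")),
            np.int64(d.const_raw("c0")), np.int64(d.const_raw("r_l")),
            np.int64(d.const_raw("one")),
            np.int64(quantize(init.V).raw), np.int64(quantize(init.AG).raw),
            np.int64(quantize(init.IP3).raw), np.int64(quantize(init.Ca).raw),
            np.int64(quantize(init.h).raw),
            out, sat)
    res = Q4_34.resolution
    series = out.astype(float) * res
    meta = {"protocol": proto.kind, "engine": "digital", "dt": dt,
            "saturation_total": int(total_sat),
            "astro": {f: getattr(d.astro, f) for f in d.astro.__dataclass_fields__},
            "neuron": {f: getattr(d.neuron, f) for f in d.neuron.__dataclass_fields__}}
    if n and (sat > 0).mean() > 0.01:
        meta["warning"] = ("more than 1% of steps saturated Q4.34 registers; "
                           "the emulated dynamics are unreliable")
    if return_raw:
        meta["raw"] = out
    return Trace(t=t, V=series[0], AG=series[1], IP3=series[2], Ca=series[3],
                 h=series[4], m_inf3=series[5], n_inf3=series[6],
                 J_pump=series[7], J_chan=series[8], J_leak=series[9],
                 dt=dt, meta=meta, saturations=sat)
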