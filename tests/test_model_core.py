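"""Reference-model unit tests: pointwise functions against hand-derived
values, closed-form oracles, and trace-level invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import astroca as ac
from astroca.errors import DomainError, ValidationError

P = ac.AstroParams()
N = ac.NeuronParams()


class TestPointwise:
    def test_q2_matches_direct_evaluation(self):
        # d2*(ip3+d1)/(ip3+d3) at the baseline IP3 of 0.16 uM
        assert ac.compute_q2(0.16, P) == pytest.approx(0.27570, abs=1e-4)
        assert ac.compute_q2(0.0, P) == pytest.approx(1.049 * 0.13 / 0.9434, abs=1e-4)
        # rational-function asymptote
        assert ac.compute_q2(1e9, P) == pytest.approx(P.d2, rel=1e-6)

    def test_q2_rejects_negative_ip3(self):
        with pytest.raises(DomainError):
            ac.compute_q2(-0.1, P)

    def test_gating_half_saturation_points(self):
        m, n, h, tau = ac.gating_steady_states(P.d1, P.d5, P)
        assert m == pytest.approx(0.5)
        assert n == pytest.approx(0.5)
        q2 = ac.compute_q2(0.3, P)
        _, _, h, _ = ac.gating_steady_states(0.3, q2, P)
        assert h == pytest.approx(0.5)

    @given(ip3=st.floats(0, 2), ca=st.floats(0, 1.6))
    @settings(max_examples=200, deadline=None)
    def test_gates_bounded_and_tau_positive(self, ip3, ca):
        m, n, h, tau = ac.gating_steady_states(ip3, ca, P)
        assert 0 <= m <= 1 and 0 <= n <= 1 and 0 <= h <= 1
        assert tau > 0

    def test_pump_half_max_at_k_er(self):
        _, _, jp = ac.compute_fluxes(P.k_ER, 0.5, 0.3, P)
        assert jp == pytest.approx(P.v_ER / 2)
        assert jp == pytest.approx(0.4)

    def test_fluxes_vanish_when_er_is_drained(self):
        ca_star = P.c0 / (1 + P.c1)
        jc, jl, _ = ac.compute_fluxes(ca_star, 0.8, 0.5, P)
        assert jc == pytest.approx(0.0, abs=1e-12)
        assert jl == pytest.approx(0.0, abs=1e-12)

    def test_channel_closed_when_h_zero(self):
        jc, _, _ = ac.compute_fluxes(0.3, 0.0, 1.0, P)
        assert jc == 0.0

    def test_baseline_is_equilibrium_of_ag_and_ip3(self):
        s = ac.SystemState(AG=0.0, IP3=P.IP3_star, Ca=0.1, h=0.8)
        d_ag, d_ip3, _, _ = ac.astro_derivatives(s, P)
        assert d_ag == 0.0
        assert d_ip3 == 0.0

    def test_h_inf_is_fixed_point_of_h(self):
        ip3, ca = 0.4, 0.2
        _, _, h_inf, _ = ac.gating_steady_states(ip3, ca, P)
        s = ac.SystemState(IP3=ip3, Ca=ca, h=h_inf)
        _, _, _, d_h = ac.astro_derivatives(s, P)
        assert d_h == pytest.approx(0.0, abs=1e-14)


class TestNeuron:
    def test_no_drive_never_spikes(self):
        p = N.replace(I_syn=0.0)
        v = 0.0
        for _ in range(1000):
            v, spiked = ac.neuron_step(v, p, 1e-3)
            assert not spiked
        assert v == 0.0

    def test_threshold_boundary_resets_immediately(self):
        v, spiked = ac.neuron_step(N.V_th, N, 1e-3)
        assert spiked and v == N.V_reset

    def test_euler_isi_matches_closed_form(self):
        dt = 1e-4
        v, n_steps, spikes = 0.0, 0, []
        for i in range(10000):
            v, spiked = ac.neuron_step(v, N, dt)
            if spiked:
                spikes.append(i)
        isi_sim = np.diff(spikes).mean() * dt
        assert abs(isi_sim - N.isi()) <= 2 * dt
        assert N.isi() == pytest.approx(0.1 * math.log(1.25))

    def test_unstable_dt_warns(self):
        with pytest.warns(UserWarning):
            ac.neuron_step(0.0, N, dt=0.2)


class TestSimulateReference:
    def test_clamp_trace_reproduces_waveform_and_invariants(self):
        proto = ac.ip3_clamp([(100.0, 0.3), (100.0, 0.7)])
        tr = ac.simulate_reference(proto, dt_out=1e-2)
        assert np.all(tr.IP3[tr.t < 100.0] == 0.3)
        assert np.all(tr.IP3[tr.t >= 100.0] == 0.7)
        # positivity / boundedness of the calcium subsystem
        assert np.all(tr.Ca > 0) and np.all(tr.Ca <= P.ca_max + 1e-9)
        assert np.all((tr.h >= 0) & (tr.h <= 1))
        assert len(tr) == 20000

    def test_quiescent_spike_protocol_holds_baseline(self):
        proto = ac.Protocol(kind="spike_driven", T_total=50.0, spike_times=())
        tr = ac.simulate_reference(proto, dt_out=1e-2)
        assert np.allclose(tr.AG, 0.0, atol=1e-12)
        assert np.allclose(tr.IP3, P.IP3_star, atol=1e-7)

    def test_single_spike_gives_exponential_ag_transient(self):
        t0 = 5.0
        proto = ac.Protocol(kind="spike_driven", T_total=40.0, spike_times=(t0,))
        tr = ac.simulate_reference(proto, dt_out=1e-2)
        after = tr.t > t0
        expected = P.r_AG * np.exp(-(tr.t[after] - t0) / P.tau_AG)
        assert np.allclose(tr.AG[after], expected, atol=1e-8)
        assert np.allclose(tr.AG[tr.t < t0], 0.0, atol=1e-12)

    def test_zero_duration_protocol_gives_empty_trace(self):
        proto = ac.Protocol(kind="spike_driven", T_total=0.0, spike_times=())
        assert len(ac.simulate_reference(proto)) == 0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValidationError):
            ac.simulate_reference(ac.ip3_clamp([(10.0, 0.3)]), dt_out=-1.0)


class TestEulerTwin:
    def test_self_convergence_under_step_refinement(self):
        # halving dt twice changes the calcium trace by far less than 1% NRMSE
        proto = ac.ip3_clamp([(120.0, 0.625)])
        coarse = ac.simulate_euler_reference(proto, dt=1e-3)
        fine = ac.simulate_euler_reference(proto, dt=1e-4)
        ca_fine = fine.Ca[::10]
        err = ac.rmse(ca_fine, coarse.Ca) / (ca_fine.max() - ca_fine.min())
        assert err < 0.01

    def test_matches_adaptive_reference(self):
        proto = ac.ip3_clamp([(120.0, 0.625)])
        eu = ac.simulate_euler_reference(proto, dt=1e-3)
        rk = ac.simulate_reference(proto, dt_out=1e-3)
        assert ac.nrmse(rk.Ca, eu.Ca) < 0.01


def test_fm_frequency_monotone_in_ip3():
    """Oscillation frequency grows with the clamp level under the FM preset."""
    fm = ac.preset_astro_params("fm")
    freqs = {}
    for lvl in (0.5, 0.8):
        tr = ac.simulate_reference(ac.ip3_clamp([(300.0, lvl)]), astro=fm, dt_out=1e-2)
        freqs[lvl] = ac.oscillation_stats(tr).mean_frequency
    assert freqs[0.8] >= freqs[0.5] > 0
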