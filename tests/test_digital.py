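"""Digital-emulator tests: bit-exact determinism, agreement between the
pure-Python step and the compiled core, fixed points, and convergence
against the floating-point Euler twin."""

import numpy as np
import pytest

import astroca as ac
from astroca.digital import DigitalState, step_digital
from astroca.fixed import quantize


def test_bit_exact_determinism(designs_default):
    proto = ac.ip3_clamp([(20.0, 0.625)])
    a = ac.run_digital(proto, designs_default, return_raw=True)
    b = ac.run_digital(proto, designs_default, return_raw=True)
    assert np.array_equal(a.meta["raw"], b.meta["raw"])


def test_python_step_matches_compiled_core(designs_default):
    """300 spike-mode steps, all five state registers bit-identical."""
    proto = ac.spike_driven(ac.NeuronParams(), 0.3, rate_scale=0.25)
    raw = ac.run_digital(proto, designs_default, return_raw=True).meta["raw"]
    spike_steps = set(int(t / designs_default.dt) for t in proto.spike_times)
    init = ac.InitialState()
    st = DigitalState(V=quantize(init.V), AG=quantize(init.AG),
                      IP3=quantize(init.IP3), Ca=quantize(init.Ca),
                      h=quantize(init.h))
    for i in range(300):
        for j, name in enumerate(("V", "AG", "IP3", "Ca", "h")):
            assert getattr(st, name).raw == raw[j, i], f"{name} at step {i}"
        st = step_digital(st, designs_default, spike=(i in spike_steps))


def test_quiescent_baseline_is_fixed_point(designs_default):
    """With no spikes and the state at the quantized baseline, IP3 moves by
    at most 2 ulp over a thousand steps."""
    proto = ac.Protocol(kind="spike_driven", T_total=1.0, spike_times=())
    tr = ac.run_digital(proto, designs_default, return_raw=True)
    ip3_raw = tr.meta["raw"][2]
    assert np.abs(ip3_raw - ip3_raw[0]).max() <= 2
    assert np.all(tr.meta["raw"][1] == 0)  # AG stays exactly 0


def test_spike_increments_ag_by_quantized_r_ag(designs_default):
    proto = ac.Protocol(kind="spike_driven", T_total=0.5, spike_times=(0.1,))
    tr = ac.run_digital(proto, designs_default)
    step = int(0.1 / designs_default.dt)
    assert tr.AG[step] == 0.0
    assert tr.AG[step + 1] == pytest.approx(0.018, abs=1e-5)
    # exponential decay afterwards
    assert 0 < tr.AG[-1] < tr.AG[step + 1]


def test_zero_duration_protocol_gives_empty_trace(designs_default):
    proto = ac.Protocol(kind="spike_driven", T_total=0.0, spike_times=())
    tr = ac.run_digital(proto, designs_default)
    assert len(tr) == 0
    assert tr.meta["saturation_total"] == 0


def test_no_saturation_in_physiological_runs(fig8_bundle):
    assert fig8_bundle.digital.meta["saturation_total"] == 0
    assert "warning" not in fig8_bundle.digital.meta


def test_step_convergence_on_fm_protocol():
    """Halving dt changes the digital calcium trace by < 2% NRMSE."""
    astro = ac.preset_astro_params("fm")
    proto = ac.ip3_clamp([(150.0, 0.4), (150.0, 0.6)])
    d1 = ac.build_designs(astro=astro, dt=1e-3)
    d2 = ac.build_designs(astro=astro, dt=5e-4)
    tr1 = ac.run_digital(proto, d1)
    tr2 = ac.run_digital(proto, d2)
    err = ac.rmse(tr2.Ca[::2], tr1.Ca) / (np.max(tr2.Ca) - np.min(tr2.Ca))
    assert err < 0.02


def test_digital_tracks_euler_twin(fig9_bundles):
    """Against the float64 Euler twin at the same dt the only differences
    are quantization and PWL/SCM approximation; calcium NRMSE stays small."""
    bundle = fig9_bundles["fig9_fm"]
    astro = ac.AstroParams(**bundle.meta["astro"])
    eu = ac.simulate_euler_reference(bundle.protocol, astro=astro, dt=1e-3)
    err = ac.nrmse(eu.Ca, bundle.digital.Ca)
    assert err < 0.05


def test_clamp_mode_passes_quantized_waveform(designs_default):
    proto = ac.ip3_clamp([(1.0, 0.3), (1.0, 0.7)])
    tr = ac.run_digital(proto, designs_default)
    assert np.allclose(tr.IP3[tr.t < 1.0], 0.3, atol=1e-9)
    assert np.allclose(tr.IP3[tr.t >= 1.0], 0.7, atol=1e-9)
    assert np.all(tr.V == 0.0)


def test_design_serialization_round_trip(designs_default, tmp_path):
    path = tmp_path / "designs.json"
    designs_default.to_json(path)
    import json
    d = json.loads(path.read_text())
    assert set(d["pwl"]) == {"q2", "m_inf", "n_inf", "j_pump_hill"}
    assert set(d["const_plans"]) >= {"dt", "a2", "r_c", "v_er"}
    for pf in d["pwl"].values():
        assert pf["max_abs_err"] <= 2e-4
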