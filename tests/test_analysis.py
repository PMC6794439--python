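"""Analysis tests on constructed signals with known peak structure, plus
regime/mode classification on simulated traces."""

import numpy as np
import pytest

import astroca as ac
from astroca.analysis import OscillationStats, classify_modulation
from astroca.errors import ValidationError


def make_stats(amps, period, t0=100.0):
    times = t0 + period * np.arange(len(amps))
    return OscillationStats(n_peaks=len(amps), peak_times=times,
                            peak_amplitudes=np.asarray(amps, float),
                            inter_peak_intervals=np.diff(times),
                            window=(t0, t0 + period * len(amps)))


class TestDetectPeaks:
    def test_constant_series_has_no_peaks(self):
        t = np.arange(0, 300, 0.05)
        pt, amps = ac.detect_peaks(t, np.full_like(t, 0.2))
        assert len(pt) == 0

    def test_sinusoid_with_known_period(self):
        # 0.05 Hz, amplitude 0.3 uM, 400 s record, 100 s burn-in -> 15 peaks
        t = np.arange(0, 400, 0.05)
        ca = 0.3 + 0.3 * np.sin(2 * np.pi * 0.05 * t)
        pt, amps = ac.detect_peaks(t, ca, burn_in=100.0)
        assert len(pt) == 15
        assert np.diff(pt).mean() == pytest.approx(20.0, abs=0.05)
        # peak-to-trough amplitude of a sinusoid is twice its amplitude
        assert amps[1:] == pytest.approx(0.6, abs=1e-3)

    def test_empty_window_is_empty_result(self):
        pt, amps = ac.detect_peaks(np.arange(3) * 0.1, np.zeros(3), burn_in=10.0)
        assert len(pt) == 0 and len(amps) == 0


class TestRegime:
    def test_synthetic_damped_ringing(self):
        t = np.arange(0, 300, 0.05)
        ca = 0.5 + np.exp(-t / 20.0) * np.sin(2 * np.pi * t / 15.0)
        assert ac.classify_regime(t, ca) == "damped"

    def test_synthetic_sustained_oscillation(self):
        t = np.arange(0, 300, 0.05)
        ca = 0.5 + 0.3 * np.sin(2 * np.pi * t / 15.0)
        assert ac.classify_regime(t, ca) == "oscillatory"

    def test_synthetic_constant(self):
        t = np.arange(0, 300, 0.05)
        assert ac.classify_regime(t, np.full_like(t, 0.07)) == "steady"

    def test_too_short_trace_rejected(self):
        t = np.arange(0, 100, 0.05)
        with pytest.raises(ValidationError):
            ac.classify_regime(t, np.zeros_like(t), burn_in=100.0)


class TestModulationRule:
    def test_amplitude_only_change_is_am(self):
        call = classify_modulation(make_stats([0.4] * 5, 20.0),
                                   make_stats([0.8] * 5, 20.5))
        assert call.mode == "AM"

    def test_frequency_only_change_is_fm(self):
        call = classify_modulation(make_stats([0.5] * 5, 30.0),
                                   make_stats([0.52] * 5, 15.0))
        assert call.mode == "FM"

    def test_both_changes_are_afm(self):
        call = classify_modulation(make_stats([0.4] * 5, 30.0),
                                   make_stats([0.7] * 5, 18.0))
        assert call.mode == "AFM"

    def test_no_change_is_none(self):
        call = classify_modulation(make_stats([0.5] * 5, 20.0),
                                   make_stats([0.51] * 5, 20.2))
        assert call.mode == "none"

    def test_non_oscillatory_input_yields_diagnostic(self):
        call = classify_modulation(make_stats([0.5], 20.0),
                                   make_stats([0.5] * 5, 20.0))
        assert call.mode == "none"
        assert "non-oscillatory" in call.diagnostic

    def test_reproducible_from_change_fields(self):
        lo, hi = make_stats([0.4] * 5, 20.0), make_stats([0.9] * 5, 10.0)
        call = classify_modulation(lo, hi)
        da = abs(hi.mean_amplitude - lo.mean_amplitude) / lo.mean_amplitude
        df = abs(hi.mean_frequency - lo.mean_frequency) / lo.mean_frequency
        assert call.amplitude_change == pytest.approx(da)
        assert call.frequency_change == pytest.approx(df)


class TestPhasePlane:
    def test_unknown_pair_lists_valid_pairs(self, oscillatory_pair):
        ref, _ = oscillatory_pair
        with pytest.raises(ValidationError, match="valid pairs"):
            ac.phase_plane(ref, ("Ca", "V"))

    def test_steady_trajectory_collapses_to_point(self, clamp_references):
        steady = ac.phase_plane(clamp_references[0.125], ("Ca", "h"))
        osc = ac.phase_plane(clamp_references[0.625], ("Ca", "h"))
        diag = lambda a: np.hypot(np.ptp(a[:, 0]), np.ptp(a[:, 1]))
        assert diag(steady) < 0.01 * diag(osc)

    def test_limit_cycle_closes_on_itself(self, oscillatory_pair):
        """First and last post-transient cycles of the reference overlap."""
        ref, _ = oscillatory_pair
        stats = ac.oscillation_stats(ref)
        pt = stats.peak_times
        period = np.diff(pt).mean()
        first = ac.phase_plane(ref, ("Ca", "h"), burn_in=pt[0] - ref.t[0])
        first = first[: int(period / ref.dt)]
        last = ac.phase_plane(ref, ("Ca", "h"), burn_in=pt[-2] - ref.t[0])
        last = last[: int(period / ref.dt)]
        d = ac.trajectory_hausdorff(first, last)
        assert d < 0.02 * np.hypot(np.ptp(first[:, 0]), np.ptp(first[:, 1]))

    def test_channel_axis_is_zero_when_h_is_zero(self, designs_default):
        jc, _, _ = ac.compute_fluxes(np.linspace(0, 1.5, 50), 0.0, 0.8,
                                     ac.AstroParams())
        assert np.all(jc == 0.0)


def test_modulation_windows_guard_clamp_edges(fig9_bundles):
    """Per-level stats exclude the 30 s after each step edge."""
    call = fig9_bundles["fig9_afm"].mode_call_reference
    lo_stats = call.per_level[0.4]
    hi_stats = call.per_level[0.6]
    assert all((t < 150) or (t >= 380) for t in lo_stats.peak_times)
    assert all(180 <= t < 350 for t in hi_stats.peak_times)
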