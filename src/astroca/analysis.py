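"""Quantifying calcium responses: peaks, regimes, modulation modes.

The information-encoding readout of the model is carried by calcium
oscillations: their peak amplitudes (AM), their inter-peak intervals
(FM), or both (AFM).  This module extracts those statistics from traces
and applies the package's operational decision rules:

* a trace is *steady* when no peaks survive the burn-in, *damped* when
  its peaks decay monotonically to (near) nothing, *oscillatory*
  otherwise;
* a protocol exhibits AM when stepping the stimulus changes the mean
  oscillation amplitude by more than ``amp_thresh`` (relative) while the
  mean frequency stays within ``freq_thresh``, FM in the converse case,
  and AFM when both change.

The thresholds (default 15% each) are this package's quantitative
operationalization of the qualitative published narrative ("amplitude
increases while frequency is practically constant"); they are exposed on
every entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ValidationError
from .protocols import Protocol
from .trace import Trace

__all__ = ["OscillationStats", "ModeCall", "detect_peaks", "oscillation_stats",
           "classify_regime", "classify_modulation", "analyze_modulation",
           "phase_plane", "trajectory_hausdorff",
           "DEFAULT_PROMINENCE", "DEFAULT_BURN_IN", "DEFAULT_EDGE_GUARD"]

DEFAULT_PROMINENCE = 0.05   # uM; small relative to the ~0.5-1 uM oscillations
DEFAULT_BURN_IN = 100.0     # s; covers the initial-condition transient
DEFAULT_EDGE_GUARD = 30.0   # s excluded after each clamp edge

PHASE_PAIRS = (("Ca", "h"), ("Ca", "J_chan"), ("h", "J_chan"))


@dataclass
class OscillationStats:
    """Peak statistics of a calcium series over one analysis window."""

    n_peaks: int
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray       # peak minus preceding trough (uM)
    inter_peak_intervals: np.ndarray  # s
    window: tuple[float, float]
    mean_amplitude: float = field(init=False)
    mean_frequency: float = field(init=False)
    amplitude_cv: float = field(init=False)
    interval_cv: float = field(init=False)

    def __post_init__(self) -> None:
        amps = np.asarray(self.peak_amplitudes, float)
        ivals = np.asarray(self.inter_peak_intervals, float)
        self.mean_amplitude = float(amps.mean()) if amps.size else 0.0
        self.mean_frequency = float(1.0 / ivals.mean()) if ivals.size else 0.0
        self.amplitude_cv = float(amps.std() / amps.mean()) if amps.size and amps.mean() else 0.0
        self.interval_cv = float(ivals.std() / ivals.mean()) if ivals.size and ivals.mean() else 0.0

    @property
    def oscillatory(self) -> bool:
        """At least two peaks, so that a frequency is defined."""
        return self.n_peaks >= 2

    def to_dict(self) -> dict:
        return {"n_peaks": self.n_peaks,
                "peak_times": np.asarray(self.peak_times).tolist(),
                "peak_amplitudes": np.asarray(self.peak_amplitudes).tolist(),
                "inter_peak_intervals": np.asarray(self.inter_peak_intervals).tolist(),
                "mean_amplitude": self.mean_amplitude,
                "mean_frequency": self.mean_frequency,
                "amplitude_cv": self.amplitude_cv,
                "interval_cv": self.interval_cv,
                "window": list(self.window)}


@dataclass
class ModeCall:
    """Modulation-mode classification between a low and a high stimulus level."""

    mode: str                      # "AM" | "FM" | "AFM" | "none"
    amplitude_change: float        # relative, vs the low level
    frequency_change: float
    amp_thresh: float
    freq_thresh: float
    per_level: dict = field(default_factory=dict)
    diagnostic: str = ""

    def to_dict(self) -> dict:
        return {"mode": self.mode, "amplitude_change": self.amplitude_change,
                "frequency_change": self.frequency_change,
                "amp_thresh": self.amp_thresh, "freq_thresh": self.freq_thresh,
                "diagnostic": self.diagnostic,
                "per_level": {str(k): v.to_dict() if isinstance(v, OscillationStats)
                              else v for k, v in self.per_level.items()}}


def detect_peaks(t: np.ndarray, ca: np.ndarray, burn_in: float = DEFAULT_BURN_IN,
                 prominence: float = DEFAULT_PROMINENCE):
    """Find calcium peaks after ``burn_in``; amplitudes are measured from
    each peak to its preceding trough (or to the window start for the
    first peak).  Returns ``(peak_times, amplitudes)``."""
    t = np.asarray(t, float)
    ca = np.asarray(ca, float)
    sel = t >= (t[0] + burn_in if t.size else 0.0)
    tw, cw = t[sel], ca[sel]
    if tw.size < 3:
        return np.empty(0), np.empty(0)
    idx, _ = find_peaks(cw, prominence=prominence)
    amps = np.empty(len(idx))
    prev = 0
    for j, p in enumerate(idx):
        amps[j] = cw[p] - cw[prev:p + 1].min()
        prev = p
    return tw[idx], amps


def oscillation_stats(trace_or_t, ca=None, window: tuple[float, float] | None = None,
                      burn_in: float = DEFAULT_BURN_IN,
                      prominence: float = DEFAULT_PROMINENCE) -> OscillationStats:
    """Peak statistics over ``window`` (after ``burn_in`` from the window
    start).  Accepts a Trace or explicit (t, ca) arrays."""
    if isinstance(trace_or_t, Trace):
        t, ca = trace_or_t.t, trace_or_t.Ca
    else:
        t = np.asarray(trace_or_t, float)
        ca = np.asarray(ca, float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, ca = t[m], ca[m]
    else:
        window = (float(t[0]), float(t[-1])) if t.size else (0.0, 0.0)
    if t.size and burn_in >= (t[-1] - t[0]):
        raise ValidationError("burn_in must be shorter than the analysis window")
    pt, amps = detect_peaks(t, ca, burn_in=burn_in, prominence=prominence)
    return OscillationStats(n_peaks=len(pt), peak_times=pt, peak_amplitudes=amps,
                            inter_peak_intervals=np.diff(pt),
                            window=(float(window[0]), float(window[1])))


def classify_regime(trace_or_t, ca=None, burn_in: float = DEFAULT_BURN_IN,
                    prominence: float = DEFAULT_PROMINENCE) -> str:
    """Classify a constant-stimulus calcium trace.

    *damped*: at least two peaks whose amplitudes decay monotonically, with
    no residual oscillation in the final fifth of the trace (largest
    remaining amplitude below 10% of the first peak).  *steady*: no peaks
    after the burn-in.  *oscillatory*: everything else.  The damped test
    runs on the full trace because a ringing transient typically dies out
    before the burn-in ends, and it uses a 5x finer peak prominence since
    ring-down peaks are shallow by nature.
    """
    if isinstance(trace_or_t, Trace):
        t, ca = trace_or_t.t, trace_or_t.Ca
    else:
        t = np.asarray(trace_or_t, float)
        ca = np.asarray(ca, float)
    if t.size and (t[-1] - t[0]) < 2 * burn_in:
        raise ValidationError("trace must be at least twice the burn-in long")
    full_t, full_amp = detect_peaks(t, ca, burn_in=0.0, prominence=prominence / 5)
    post_t, _ = detect_peaks(t, ca, burn_in=burn_in, prominence=prominence)
    if len(full_t) >= 2:
        # the first amplitude is measured from the window start rather than
        # a true trough, so exclude it from the decay test when possible
        amps = full_amp[1:] if len(full_amp) >= 3 else full_amp
        if np.all(np.diff(amps) <= 1e-12):
            tail_start = t[0] + 0.8 * (t[-1] - t[0])
            tail = full_amp[full_t >= tail_start]
            tail_amp = tail.max() if tail.size else 0.0
            if tail_amp < 0.1 * amps[0]:
                return "damped"
    if len(post_t) == 0:
        return "steady"
    return "oscillatory"


def classify_modulation(stats_low: OscillationStats, stats_high: OscillationStats,
                        amp_thresh: float = 0.15,
                        freq_thresh: float = 0.15) -> ModeCall:
    """Call the encoding mode from low- and high-stimulus statistics.

    Relative changes are measured against the low level.  Non-oscillatory
    input yields mode "none" with a diagnostic instead of an error.
    """
    per_level = {"low": stats_low, "high": stats_high}
    if not (stats_low.oscillatory and stats_high.oscillatory):
        which = [k for k, s in per_level.items() if not s.oscillatory]
        return ModeCall(mode="none", amplitude_change=np.nan,
                        frequency_change=np.nan, amp_thresh=amp_thresh,
                        freq_thresh=freq_thresh, per_level=per_level,
                        diagnostic=f"non-oscillatory window(s): {which}; "
                                   "a modulation mode needs >= 2 peaks per level")
    da = abs(stats_high.mean_amplitude - stats_low.mean_amplitude) / stats_low.mean_amplitude
    df = abs(stats_high.mean_frequency - stats_low.mean_frequency) / stats_low.mean_frequency
    if da > amp_thresh and df <= freq_thresh:
        mode = "AM"
    elif df > freq_thresh and da <= amp_thresh:
        mode = "FM"
    elif da > amp_thresh and df > freq_thresh:
        mode = "AFM"
    else:
        mode = "none"
    return ModeCall(mode=mode, amplitude_change=float(da), frequency_change=float(df),
                    amp_thresh=amp_thresh, freq_thresh=freq_thresh,
                    per_level=per_level)


def _pooled_stats(trace: Trace, windows: list[tuple[float, float]],
                  prominence: float) -> OscillationStats:
    """Peak statistics pooled over disjoint windows of one stimulus level;
    inter-peak intervals never straddle a window boundary."""
    times, amps, ivals = [], [], []
    for w0, w1 in windows:
        s = oscillation_stats(trace, window=(w0, w1), burn_in=0.0,
                              prominence=prominence)
        times.append(s.peak_times)
        amps.append(s.peak_amplitudes)
        ivals.append(s.inter_peak_intervals)
    times = np.concatenate(times) if times else np.empty(0)
    lo = min((w0 for w0, _ in windows), default=0.0)
    hi = max((w1 for _, w1 in windows), default=0.0)
    return OscillationStats(n_peaks=len(times), peak_times=times,
                            peak_amplitudes=np.concatenate(amps) if amps else np.empty(0),
                            inter_peak_intervals=np.concatenate(ivals) if ivals else np.empty(0),
                            window=(lo, hi))


def analyze_modulation(trace: Trace, proto: Protocol,
                       burn_in: float = DEFAULT_BURN_IN,
                       edge_guard: float = DEFAULT_EDGE_GUARD,
                       prominence: float = DEFAULT_PROMINENCE,
                       amp_thresh: float = 0.15,
                       freq_thresh: float = 0.15) -> ModeCall:
    """Modulation-mode call for a two-level clamp protocol.

    Analysis windows start ``edge_guard`` seconds after each clamp edge
    (``burn_in`` after t=0) and are pooled per stimulus level; the call
    compares the lowest against the highest level.
    """
    if proto.kind != "ip3_clamp":
        raise ValidationError("modulation analysis requires an ip3_clamp protocol")
    levels = sorted(set(proto.levels))
    if len(levels) < 2:
        raise ValidationError("modulation analysis needs at least two clamp levels")
    lo_level, hi_level = levels[0], levels[-1]
    windows: dict[float, list[tuple[float, float]]] = {}
    for i, (t0, t1, lvl) in enumerate(proto.level_windows()):
        guard = burn_in if i == 0 else edge_guard
        if t1 - t0 > guard:
            windows.setdefault(lvl, []).append((t0 + guard, t1))
    call = classify_modulation(
        _pooled_stats(trace, windows.get(lo_level, []), prominence),
        _pooled_stats(trace, windows.get(hi_level, []), prominence),
        amp_thresh=amp_thresh, freq_thresh=freq_thresh)
    call.per_level = {lo_level: call.per_level["low"], hi_level: call.per_level["high"]}
    return call


def phase_plane(trace: Trace, pair: tuple[str, str] = ("Ca", "h"),
                burn_in: float = DEFAULT_BURN_IN) -> np.ndarray:
    """Post-transient trajectory in one of the standard phase planes.

    Returns an (n, 2) array of paired samples (no resampling).
    """
    if tuple(pair) not in PHASE_PAIRS:
        raise ValidationError(f"unknown phase-plane pair {pair!r}; "
                              f"valid pairs: {PHASE_PAIRS}")
    sel = trace.t >= (trace.t[0] + burn_in if len(trace) else 0.0)
    return np.column_stack([trace.series(pair[0])[sel], trace.series(pair[1])[sel]])


def trajectory_hausdorff(a: np.ndarray, b: np.ndarray,
                         max_points: int = 2000) -> float:
    """Symmetric Hausdorff distance between two planar trajectories
    (uniformly subsampled to at most ``max_points`` each)."""
    from scipy.spatial.distance import directed_hausdorff

    def sub(x):
        x = np.asarray(x, float)
        if len(x) > max_points:
            x = x[np.linspace(0, len(x) - 1, max_points).astype(int)]
        return x

    a, b = sub(a), sub(b)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
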