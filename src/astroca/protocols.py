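"""Stimulation protocols.

Three kinds of stimulation are supported:

``ip3_clamp``
    The astrocyte's IP3 level is clamped to a piecewise-constant waveform
    (a staircase of levels); the 2-AG and IP3 production equations are
    bypassed.  This is how the regime and modulation-mode experiments
    drive the cell.

``spike_driven``
    An integrate-and-fire neuron with constant drive fires periodically;
    its spikes (thinned by ``rate_scale``) each release a fixed quantity
    of 2-AG, which produces IP3 inside the astrocyte.  The protocol owns
    the delivered spike-time list so the reference and digital simulators
    integrate the identical drive.

``spike_file``
    As ``spike_driven`` but with a user-supplied list of spike times
    (plain text, one time in seconds per line).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .params import NeuronParams

__all__ = [
    "Protocol",
    "ip3_clamp",
    "staircase",
    "spike_driven",
    "spike_file",
    "if_spike_times",
    "fig6_protocol",
    "fig9_protocol",
    "FIG6_INCREMENTS",
]

#: Per-interval IP3 increments of the incremental staircase experiment.
#: Read cumulatively they give clamp levels 0.125, 0.4, 0.53125, 0.625, 1.2 uM.
FIG6_INCREMENTS = (0.125, 0.275, 0.13125, 0.09375, 0.575)


@dataclass(frozen=True)
class Protocol:
    """A stimulation protocol.

    Attributes
    ----------
    kind:
        ``"ip3_clamp"``, ``"spike_driven"`` or ``"spike_file"``.
    segments:
        For clamp protocols, a tuple of ``(duration_s, ip3_level_uM)``.
    spike_times:
        For spike protocols, strictly increasing delivery times (s).
    T_total:
        Total protocol duration (s).
    """

    kind: str
    T_total: float
    segments: tuple[tuple[float, float], ...] = ()
    spike_times: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("ip3_clamp", "spike_driven", "spike_file"):
            raise ValidationError(f"unknown protocol kind {self.kind!r}")
        if self.T_total < 0:
            raise ValidationError("T_total must be non-negative")
        if self.kind == "ip3_clamp":
            if self.T_total > 0 and not self.segments:
                raise ValidationError("clamp protocol needs at least one segment")
            for dur, level in self.segments:
                if dur <= 0:
                    raise ValidationError("segment durations must be positive")
                if level < 0:
                    raise ValidationError("IP3 levels must be non-negative")
            total = sum(d for d, _ in self.segments)
            if abs(total - self.T_total) > 1e-9:
                raise ValidationError(
                    f"segment durations sum to {total} s but T_total is {self.T_total} s")
        else:
            st = np.asarray(self.spike_times, float)
            if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0):
                raise ValidationError("spike times must be non-negative and strictly increasing")
            if st.size and st[-1] >= self.T_total:
                raise ValidationError("spike times must lie before T_total")

    # -- clamp helpers -------------------------------------------------
    @property
    def edges(self) -> np.ndarray:
        """Segment boundary times including 0 and T_total (clamp protocols)."""
        durs = np.asarray([d for d, _ in self.segments], float)
        return np.concatenate([[0.0], np.cumsum(durs)])

    @property
    def levels(self) -> np.ndarray:
        return np.asarray([lvl for _, lvl in self.segments], float)

    def ip3_at(self, t: np.ndarray) -> np.ndarray:
        """Clamp waveform sampled at times ``t``."""
        if self.kind != "ip3_clamp":
            raise ValidationError("ip3_at is defined for clamp protocols only")
        t = np.asarray(t, float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, len(self.segments) - 1)
        return self.levels[idx]

    def level_windows(self) -> list[tuple[float, float, float]]:
        """List of ``(t0, t1, level)`` for each clamp segment."""
        e = self.edges
        return [(e[i], e[i + 1], lvl) for i, lvl in enumerate(self.levels)]


# ---------------------------------------------------------------------------
# constructors


def ip3_clamp(segments: Sequence[tuple[float, float]]) -> Protocol:
    """Piecewise-constant IP3 clamp from ``(duration, level)`` pairs."""
    segs = tuple((float(d), float(l)) for d, l in segments)
    return Protocol(kind="ip3_clamp", T_total=sum(d for d, _ in segs), segments=segs)


def staircase(values: Sequence[float], dwell: float, cumulative: bool = False) -> Protocol:
    """Staircase clamp: one level per ``dwell``-second interval.

    With ``cumulative=True`` the ``values`` are per-interval increments and
    the clamp level is their running sum.
    """
    levels = np.cumsum(values) if cumulative else np.asarray(values, float)
    return ip3_clamp([(dwell, float(l)) for l in levels])


def if_spike_times(neuron: NeuronParams, T_total: float) -> np.ndarray:
    """Spike times of the IF neuron under constant drive, from the closed-form
    inter-spike interval (first spike one interval after t=0)."""
    isi = neuron.isi()
    if not math.isfinite(isi):
        return np.empty(0)
    n = int(T_total / isi)
    times = isi * np.arange(1, n + 1)
    return times[times < T_total]


def spike_driven(neuron: NeuronParams, T_total: float, rate_scale: float = 0.01) -> Protocol:
    """Spike-driven protocol: IF spike train thinned by ``rate_scale``.

    Every ``round(1/rate_scale)``-th spike of the neuron is delivered to the
    astrocyte.  The published constant table gives an IF rate of ~45 Hz whose
    full delivery would push IP3 far beyond the oscillatory range, so the
    default scale 0.01 yields an effective ~0.45 Hz endocannabinoid drive and
    a steady-state IP3 of ~0.44 uM, inside the oscillatory regime.
    """
    if not 0 < rate_scale <= 1:
        raise ValidationError("rate_scale must be in (0, 1]")
    keep = max(1, int(round(1.0 / rate_scale)))
    times = if_spike_times(neuron, T_total)[keep - 1::keep]
    return Protocol(kind="spike_driven", T_total=float(T_total),
                    spike_times=tuple(times), meta={"rate_scale": rate_scale})


def spike_file(path: str | Path, T_total: float | None = None) -> Protocol:
    """Protocol from a plain-text spike-time file (one time in seconds per line)."""
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            times.append(float(line))
    if T_total is None:
        T_total = (max(times) + 1.0) if times else 0.0
    return Protocol(kind="spike_file", T_total=float(T_total), spike_times=tuple(times))


def fig6_protocol(dwell: float = 100.0,
                  increments: Sequence[float] = FIG6_INCREMENTS,
                  cumulative: bool = True,
                  rng: np.random.Generator | None = None) -> Protocol:
    """Five-level incremental IP3 staircase (100 s per level).

    By default the published per-interval increments are accumulated into
    clamp levels 0.125, 0.4, 0.53125, 0.625 and 1.2 uM.  Passing an ``rng``
    draws random increments in [0.05, 0.6] uM instead, emulating the
    "random level in each interval" variant.
    """
    if rng is not None:
        increments = rng.uniform(0.05, 0.6, size=len(increments))
    return staircase(increments, dwell, cumulative=cumulative)


def fig9_protocol(low: float = 0.4, high: float = 0.6,
                  t_step: float = 150.0, t_back: float = 350.0,
                  T_total: float = 500.0) -> Protocol:
    """Step protocol of the modulation-mode experiments: the clamp sits at
    ``low``, is raised to ``high`` during [t_step, t_back) and returns."""
    if not 0 < t_step < t_back < T_total:
        raise ValidationError("fig9 protocol needs 0 < t_step < t_back < T_total")
    return ip3_clamp([(t_step, low), (t_back - t_step, high), (T_total - t_back, low)])
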