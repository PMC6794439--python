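"""Reference-vs-digital error metrics and comparison reports.

RMSE is the plain root-mean-square difference of two equally sampled
series; NRMSE normalizes it by the range (max - min) of the *reference*
series over the evaluation window, the reference being the ground truth.
Because quantization error accumulates over time, the standard evaluation
window ends at the 10th calcium oscillation cycle of the reference trace
("ten_cycles" policy), by which point the error has settled to a nearly
constant level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DEFAULT_PROMINENCE, detect_peaks
from .errors import ValidationError
from .trace import Trace

__all__ = ["rmse", "nrmse", "ComparisonReport", "compare_traces",
           "REPORT_VARIABLES"]

#: the eight rows of the standard error report
REPORT_VARIABLES = ("V", "AG", "IP3", "J_pump", "m_inf3", "n_inf3", "h", "Ca")


def rmse(ref, test) -> float:
    """Root-mean-square error between two equal-length series."""
    ref = np.asarray(ref, float)
    test = np.asarray(test, float)
    if ref.shape != test.shape or ref.ndim != 1:
        raise ValidationError("series must be 1-d and of equal length")
    if ref.size < 2:
        raise ValidationError("series must contain at least 2 samples")
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def nrmse(ref, test) -> float:
    """RMSE normalized by the reference range (max - min)."""
    ref = np.asarray(ref, float)
    rng = float(ref.max() - ref.min()) if ref.size else 0.0
    if rng == 0.0:
        raise ValidationError("reference series has zero range")
    return rmse(ref, test) / rng


@dataclass
class ComparisonReport:
    """Per-variable RMSE/NRMSE between a reference and a digital trace."""

    rows: dict[str, dict[str, float | None]]   # var -> {"rmse", "nrmse"}
    window: tuple[float, float]
    window_policy: str
    n_samples: int
    protocol: str
    design_snapshot: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, var: str) -> dict:
        return self.rows[var]

    def to_dict(self) -> dict:
        return {"rows": self.rows, "window": list(self.window),
                "window_policy": self.window_policy,
                "n_samples": self.n_samples, "protocol": self.protocol,
                "design_snapshot": self.design_snapshot, "notes": self.notes}

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variable": v, "rmse": r["rmse"], "nrmse": r["nrmse"]}
             for v, r in self.rows.items()])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_traces(ref: Trace, dig: Trace,
                   window_policy: str = "ten_cycles",
                   window: tuple[float, float] | None = None,
                   prominence: float = DEFAULT_PROMINENCE) -> ComparisonReport:
    """Compute the eight-variable error report between two traces.

    Both traces must share the sampling step and length (the pipelines use
    the same dt by construction, so alignment is exact).  Policies:
    ``ten_cycles`` ends the window at the 10th reference calcium peak
    (falling back to the full trace with a note when fewer than 10 peaks
    exist), ``full`` uses everything, ``explicit`` uses ``window``.
    """
    if len(ref) != len(dig) or abs(ref.dt - dig.dt) > 1e-12:
        raise ValidationError("traces must share dt and length; no resampling is applied")
    if ref.meta.get("protocol") != dig.meta.get("protocol"):
        raise ValidationError("traces come from different protocols")
    notes: list[str] = []
    if window_policy == "ten_cycles":
        pk_t, _ = detect_peaks(ref.t, ref.Ca, burn_in=0.0, prominence=prominence)
        if len(pk_t) >= 10:
            win = (float(ref.t[0]), float(pk_t[9]))
        else:
            win = (float(ref.t[0]), float(ref.t[-1]))
            notes.append(f"only {len(pk_t)} reference peaks; fell back to the full window")
    elif window_policy == "full":
        win = (float(ref.t[0]), float(ref.t[-1]))
    elif window_policy == "explicit":
        if window is None:
            raise ValidationError("explicit window policy requires a window")
        win = (float(window[0]), float(window[1]))
    else:
        raise ValidationError(f"unknown window policy {window_policy!r}")
    sel = (ref.t >= win[0]) & (ref.t <= win[1])
    if sel.sum() < 2:
        raise ValidationError("evaluation window contains fewer than 2 samples")
    rows: dict[str, dict] = {}
    for var in REPORT_VARIABLES:
        r = ref.series(var)[sel]
        d = dig.series(var)[sel]
        e = rmse(r, d)
        rng = float(r.max() - r.min())
        if rng == 0.0:
            rows[var] = {"rmse": e, "nrmse": None}
            notes.append(f"{var}: reference range is zero; NRMSE undefined")
        else:
            rows[var] = {"rmse": e, "nrmse": e / rng}
    snapshot = {k: dig.meta[k] for k in ("dt", "saturation_total") if k in dig.meta}
    return ComparisonReport(rows=rows, window=win, window_policy=window_policy,
                            n_samples=int(sel.sum()),
                            protocol=str(ref.meta.get("protocol")),
                            design_snapshot=snapshot, notes=notes)
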