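"""Time-series container shared by the reference and digital simulators."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Trace", "STATE_SERIES", "DERIVED_SERIES"]

STATE_SERIES = ("V", "AG", "IP3", "Ca", "h")
DERIVED_SERIES = ("J_chan", "J_leak", "J_pump", "m_inf3", "n_inf3")

_CSV_ORDER = ("t", "V", "AG", "IP3", "Ca", "h", "J_chan", "J_leak", "J_pump",
              "m_inf3", "n_inf3")


@dataclass
class Trace:
    """Uniformly sampled trajectory of the five state variables plus the
    derived fluxes and gating signals.

    ``meta`` snapshots the parameters and protocol that produced the trace;
    ``saturations`` (digital traces only) counts fixed-point saturation
    events per sample.
    """

    t: np.ndarray
    V: np.ndarray
    AG: np.ndarray
    IP3: np.ndarray
    Ca: np.ndarray
    h: np.ndarray
    J_chan: np.ndarray
    J_leak: np.ndarray
    J_pump: np.ndarray
    m_inf3: np.ndarray
    n_inf3: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)
    saturations: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in STATE_SERIES + DERIVED_SERIES:
            if len(getattr(self, name)) != n:
                raise ValidationError(f"series {name} length differs from t")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-12):
                raise ValidationError("t must increase uniformly with step dt")

    def __len__(self) -> int:
        return len(self.t)

    def series(self, name: str) -> np.ndarray:
        """Series accessor by name (state or derived)."""
        if name not in STATE_SERIES + DERIVED_SERIES:
            raise ValidationError(
                f"unknown series {name!r}; valid: {STATE_SERIES + DERIVED_SERIES}")
        return getattr(self, name)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask selecting samples with t0 <= t <= t1."""
        return (self.t >= t0) & (self.t <= t1)

    def to_frame(self) -> pd.DataFrame:
        data = {name: getattr(self, name) for name in _CSV_ORDER}
        if self.saturations is not None:
            data["saturations"] = self.saturations
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "Trace":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
        kwargs = {name: df[name].to_numpy() for name in _CSV_ORDER if name != "t"}
        sat = df["saturations"].to_numpy() if "saturations" in df else None
        return cls(t=t, dt=dt, meta=meta or {}, saturations=sat, **kwargs)
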