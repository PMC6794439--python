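"""Model parameters for the coupled IF-neuron / astrocyte calcium system.

The astrocyte follows the De Pitta extension of the Li-Rinzel model of
IP3-receptor mediated calcium-induced calcium release (CICR): cytosolic
Ca2+ exchanges with the endoplasmic reticulum through an IP3R channel
gated by IP3 (``m_inf``), by Ca2+ itself (``n_inf``) and by a slow
inactivation variable ``h``, a SERCA pump returns Ca2+ to the store, and
a passive leak completes the loop.  Synaptic input enters through an
integrate-and-fire neuron whose spikes release the endocannabinoid 2-AG,
which in turn drives IP3 production.

All defaults are the published values for this parameter set; quantities
are in micromolar and seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

from .errors import ValidationError

__all__ = [
    "NeuronParams",
    "AstroParams",
    "InitialState",
    "MODE_PRESETS",
    "preset_astro_params",
]


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron, ``tau_m dV/dt = -V + R_m I_syn``.

    The neuron spikes when ``V`` reaches ``V_th`` and resets to ``V_reset``.
    With the default constant drive the inter-spike interval has the closed
    form ``tau_m * ln(R_m I_syn / (R_m I_syn - V_th))``.
    """

    tau_m: float = 0.1     # membrane time constant (s)
    R_m: float = 2.5       # membrane resistance (model units)
    I_syn: float = 2.0     # constant synaptic drive (model units)
    V_th: float = 1.0      # firing threshold
    V_reset: float = 0.0   # post-spike reset value

    def __post_init__(self) -> None:
        if not all(math.isfinite(getattr(self, f.name)) for f in fields(self)):
            raise ValidationError("neuron parameters must be finite")
        if self.tau_m <= 0:
            raise ValidationError("tau_m must be positive")
        if self.V_th <= self.V_reset:
            raise ValidationError("V_th must exceed V_reset")

    @property
    def drive(self) -> float:
        """Asymptotic membrane voltage ``R_m * I_syn``."""
        return self.R_m * self.I_syn

    def isi(self) -> float:
        """Closed-form inter-spike interval for constant suprathreshold drive."""
        if self.drive <= self.V_th:
            return math.inf
        return self.tau_m * math.log(self.drive / (self.drive - self.V_th))

    def replace(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AstroParams:
    """Constants of the astrocyte 2-AG / IP3 / Ca2+ / h cascade.

    Notes
    -----
    ``a2`` is stored in 1/(uM s) so that the IP3R inactivation time constant
    ``tau_h = 1 / (a2 (Q2 + Ca))`` comes out in seconds.

    ``r_C``, the maximal CICR rate, is not part of the published constant
    table.  The default 7.5 1/s is calibrated so that the model reproduces
    the published qualitative behaviour at the published stimulus levels:
    steady calcium at an IP3 clamp of 0.125 uM, sustained oscillations for
    clamps between 0.4 and 0.625 uM, damped oscillations at 1.2 uM, and
    frequency-modulated oscillations at both 0.4 and 0.6 uM under the
    FM pump/leak preset.  See docs/methods.md for the calibration scan.
    """

    tau_AG: float = 10.0      # 2-AG decay time (s)
    r_AG: float = 0.018       # 2-AG released per spike (uM)
    IP3_star: float = 0.16    # baseline IP3 (uM)
    tau_ip3: float = 7.0      # IP3 degradation time (s)
    r_ip3: float = 0.5        # IP3 production rate per unit 2-AG (1/s)
    a2: float = 0.2           # IP3R inactivation rate (1/(uM s))
    d1: float = 0.13          # IP3 dissociation constant (uM)
    d2: float = 1.049         # Ca2+ inactivation dissociation constant (uM)
    d3: float = 0.9434        # IP3 dissociation constant (uM)
    d5: float = 0.108         # Ca2+ activation dissociation constant (uM)
    c0: float = 2.0           # total free Ca2+ per cytosolic volume (uM)
    c1: float = 0.185         # ER/cytosol volume ratio
    r_L: float = 0.11         # ER leak rate (1/s)
    r_C: float = 7.5          # maximal CICR rate (1/s); see class docstring
    v_ER: float = 0.8         # maximal SERCA uptake (uM/s)
    k_ER: float = 0.1         # SERCA activation constant (uM)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"astrocyte parameter {f.name} must be finite and positive")

    @property
    def ca_max(self) -> float:
        """Upper bound on cytosolic Ca2+: the level at which the ER driving
        term ``c0 - (1 + c1) Ca`` vanishes."""
        return self.c0 / (1.0 + self.c1)

    def replace(self, **kwargs) -> "AstroParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InitialState:
    """Published initial conditions of the cascade.

    These are initial conditions only -- the (Ca, h) pair is close to, but
    not exactly on, the model's fixed point at baseline IP3.
    """

    V: float = 0.0
    AG: float = 0.0
    IP3: float = 0.16
    Ca: float = 0.071006
    h: float = 0.7791


#: Pump/leak parameter overrides that select the calcium information-encoding
#: mode: amplitude modulation (AM), frequency modulation (FM) or both (AFM).
MODE_PRESETS: Mapping[str, Mapping[str, float]] = {
    "am": {"r_L": 0.014, "k_ER": 0.1},
    "fm": {"r_L": 0.11, "k_ER": 0.064},
    "afm": {"r_L": 0.07, "k_ER": 0.1},
}


def preset_astro_params(mode: str | None = None, **overrides) -> AstroParams:
    """Astrocyte parameters for a named encoding mode, with optional overrides.

    Parameters
    ----------
    mode:
        One of ``"am"``, ``"fm"``, ``"afm"`` or None for the base table.
    """
    kw = {}
    if mode is not None:
        key = mode.lower()
        if key not in MODE_PRESETS:
            raise ValidationError(f"unknown mode preset {mode!r}; choose from {sorted(MODE_PRESETS)}")
        kw.update(MODE_PRESETS[key])
    kw.update(overrides)
    return AstroParams(**kw)
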