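"""Preset experiments: one call reproduces a published figure's protocol.

Each preset couples a stimulation protocol with a parameter set, runs the
double-precision reference and the fixed-point digital pipelines on the
identical stimulus, and gathers the standard readouts: the eight-variable
error report, regime calls per clamp level, and the modulation-mode call
for the two-level step protocols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis
from .digital import DesignSet, build_designs, run_digital
from .errors import ValidationError
from .metrics import ComparisonReport, compare_traces
from .model import simulate_reference
from .params import AstroParams, NeuronParams, preset_astro_params
from .protocols import Protocol, fig6_protocol, fig9_protocol, spike_driven
from .trace import Trace

__all__ = ["ExperimentBundle", "run_experiment", "PRESETS"]

PRESETS = ("fig6", "fig8", "fig9_am", "fig9_fm", "fig9_afm")


@dataclass
class ExperimentBundle:
    """Everything one preset run produces."""

    preset: str
    protocol: Protocol
    reference: Trace
    digital: Trace
    report: ComparisonReport
    regimes: dict | None = None          # per-level regime calls (fig6)
    mode_call_reference: analysis.ModeCall | None = None
    mode_call_digital: analysis.ModeCall | None = None
    designs: DesignSet | None = None
    meta: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Write traces (CSV), report and analysis (JSON) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reference.to_csv(out / "reference.csv")
        self.digital.to_csv(out / "digital.csv")
        self.report.to_json(out / "comparison.json")
        self.report.to_csv(out / "comparison.csv")
        summary: dict = {"preset": self.preset, "meta": self.meta}
        if self.regimes is not None:
            summary["regimes"] = self.regimes
        if self.mode_call_reference is not None:
            summary["mode_call_reference"] = self.mode_call_reference.to_dict()
        if self.mode_call_digital is not None:
            summary["mode_call_digital"] = self.mode_call_digital.to_dict()
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if self.designs is not None:
            self.designs.to_json(out / "designs.json")
        return out


def _preset_setup(preset: str, T_total: float, neuron: NeuronParams,
                  rng: np.random.Generator | None):
    if preset == "fig6":
        return fig6_protocol(rng=rng), AstroParams()
    if preset == "fig8":
        return spike_driven(neuron, T_total), AstroParams()
    if preset.startswith("fig9_"):
        return fig9_protocol(T_total=T_total), preset_astro_params(preset.split("_", 1)[1])
    raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")


def run_experiment(preset: str,
                   overrides: dict | None = None,
                   T_total: float = 500.0,
                   dt: float = 1e-3,
                   designs: DesignSet | None = None,
                   neuron: NeuronParams | None = None,
                   out_dir: str | Path | None = None,
                   seed: int | None = None,
                   window_policy: str = "ten_cycles") -> ExperimentBundle:
    """Run one named preset end to end.

    ``overrides`` replaces astrocyte parameters on top of the preset,
    ``designs`` reuses a pre-built digital design set (it must match the
    parameters), and ``seed`` randomizes the staircase levels of the
    fig6 preset (all presets are deterministic without it).
    """
    neuron = neuron or NeuronParams()
    rng = np.random.default_rng(seed) if (seed is not None and preset == "fig6") else None
    proto, astro = _preset_setup(preset, T_total, neuron, rng)
    if overrides:
        astro = astro.replace(**overrides)
    if designs is None:
        designs = build_designs(neuron, astro, dt=dt)
    ref = simulate_reference(proto, neuron, astro, dt_out=dt)
    dig = run_digital(proto, designs)
    report = compare_traces(ref, dig, window_policy=window_policy)

    regimes = None
    mode_ref = mode_dig = None
    if preset == "fig6":
        regimes = {"reference": {}, "digital": {}}
        for t0, t1, lvl in proto.level_windows():
            for label, tr in (("reference", ref), ("digital", dig)):
                m = tr.window(t0, t1)
                regimes[label][lvl] = analysis.classify_regime(
                    tr.t[m], tr.Ca[m], burn_in=analysis.DEFAULT_EDGE_GUARD)
    elif preset.startswith("fig9_"):
        mode_ref = analysis.analyze_modulation(ref, proto)
        mode_dig = analysis.analyze_modulation(dig, proto)

    bundle = ExperimentBundle(
        preset=preset, protocol=proto, reference=ref, digital=dig,
        report=report, regimes=regimes, mode_call_reference=mode_ref,
        mode_call_digital=mode_dig, designs=designs,
        meta={"T_total": T_total, "dt": dt, "seed": seed,
              "astro": {f: getattr(astro, f) for f in astro.__dataclass_fields__}})
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
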