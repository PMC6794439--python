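"""YAML/JSON configuration loading for the command-line interface.

A config file may carry any of the keys ``neuron``, ``astrocyte``,
``protocol``, ``solver`` and ``designs``; unknown keys or fields raise a
ValidationError (CLI exit code 2).  The astrocyte section accepts
``mode: am|fm|afm`` to start from a pump/leak preset before applying
explicit overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .params import AstroParams, NeuronParams, preset_astro_params
from .protocols import Protocol, ip3_clamp, spike_driven, spike_file

__all__ = ["Config", "load_config"]

_TOP_KEYS = {"neuron", "astrocyte", "protocol", "solver", "designs"}


@dataclass
class Config:
    neuron: NeuronParams
    astrocyte: AstroParams
    protocol: Protocol | None
    solver: dict = field(default_factory=dict)
    designs: dict = field(default_factory=dict)


def _build_protocol(spec: dict, neuron: NeuronParams) -> Protocol:
    kind = spec.get("kind")
    if kind == "ip3_clamp":
        try:
            return ip3_clamp(spec["segments"])
        except KeyError as e:
            raise ValidationError(f"clamp protocol missing key {e}") from e
    if kind == "spike_driven":
        return spike_driven(neuron, float(spec.get("T_total", 500.0)),
                            rate_scale=float(spec.get("rate_scale", 0.01)))
    if kind == "spike_file":
        if "path" not in spec:
            raise ValidationError("spike_file protocol requires a 'path'")
        return spike_file(spec["path"], spec.get("T_total"))
    raise ValidationError(f"unknown protocol kind {kind!r}")


def load_config(path: str | Path) -> Config:
    """Parse and validate a YAML (or JSON) config file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ValidationError(f"cannot parse config {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")

    try:
        neuron = NeuronParams(**(raw.get("neuron") or {}))
    except TypeError as e:
        raise ValidationError(f"bad neuron section: {e}") from e
    astro_spec = dict(raw.get("astrocyte") or {})
    mode = astro_spec.pop("mode", None)
    try:
        astro = preset_astro_params(mode, **astro_spec)
    except TypeError as e:
        raise ValidationError(f"bad astrocyte section: {e}") from e
    proto = _build_protocol(raw["protocol"], neuron) if "protocol" in raw else None
    return Config(neuron=neuron, astrocyte=astro, protocol=proto,
                  solver=dict(raw.get("solver") or {}),
                  designs=dict(raw.get("designs") or {}))
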