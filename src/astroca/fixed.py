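"""Two's-complement Q4.34 fixed-point scalars with saturation semantics.

All digital registers share one global 39-bit format: 1 sign bit, 4
integer bits, 34 fractional bits.  Values are stored as the raw integer
``round(x * 2^34)`` in [-2^38, 2^38 - 1]; every operation saturates at
those bounds instead of wrapping.  Rounding on quantization is
round-half-to-even; shifts inside SCM multiplication are arithmetic
(floor), matching hardware shifters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .scm import ScmPlan

__all__ = ["FixedFormat", "FixedValue", "Q4_34", "quantize",
           "fx_add", "fx_sub", "fx_mul", "fx_scm_mul"]


@dataclass(frozen=True)
class FixedFormat:
    sign_bits: int = 1
    int_bits: int = 4
    frac_bits: int = 34

    @property
    def total(self) -> int:
        return self.sign_bits + self.int_bits + self.frac_bits

    @property
    def resolution(self) -> float:
        return 2.0 ** -self.frac_bits

    @property
    def raw_max(self) -> int:
        return (1 << (self.int_bits + self.frac_bits)) - 1

    @property
    def raw_min(self) -> int:
        return -(1 << (self.int_bits + self.frac_bits))


Q4_34 = FixedFormat()


@dataclass(frozen=True)
class FixedValue:
    """An immutable fixed-point scalar: raw integer + format."""

    raw: int
    fmt: FixedFormat = Q4_34

    def __post_init__(self) -> None:
        if not self.fmt.raw_min <= self.raw <= self.fmt.raw_max:
            raise ValidationError("raw value outside the format range")

    @property
    def value(self) -> float:
        return self.raw * self.fmt.resolution

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:
        return f"FixedValue({self.value!r}, raw={self.raw})"


def _saturate(raw: int, fmt: FixedFormat, events: list | None = None) -> int:
    if raw > fmt.raw_max:
        if events is not None:
            events.append(raw)
        return fmt.raw_max
    if raw < fmt.raw_min:
        if events is not None:
            events.append(raw)
        return fmt.raw_min
    return raw


def quantize(x: float, fmt: FixedFormat = Q4_34, events: list | None = None) -> FixedValue:
    """Quantize a real number (round-half-to-even on the raw grid;
    out-of-range values saturate)."""
    if isinstance(x, float) and math.isnan(x):
        raise ValidationError("cannot quantize NaN")
    scaled = float(x) * (1 << fmt.frac_bits)
    if math.isinf(scaled):
        raw = fmt.raw_max if scaled > 0 else fmt.raw_min
        return FixedValue(_saturate(raw, fmt, events), fmt)
    floor = math.floor(scaled)
    frac = scaled - floor
    raw = floor
    if frac > 0.5 or (frac == 0.5 and (floor & 1)):
        raw += 1
    return FixedValue(_saturate(raw, fmt, events), fmt)


def _check_fmt(a: FixedValue, b: FixedValue) -> None:
    if a.fmt != b.fmt:
        raise ValidationError("operands must share one fixed-point format")


def fx_add(a: FixedValue, b: FixedValue, events: list | None = None) -> FixedValue:
    """Exact raw addition, then saturation."""
    _check_fmt(a, b)
    return FixedValue(_saturate(a.raw + b.raw, a.fmt, events), a.fmt)


def fx_sub(a: FixedValue, b: FixedValue, events: list | None = None) -> FixedValue:
    _check_fmt(a, b)
    return FixedValue(_saturate(a.raw - b.raw, a.fmt, events), a.fmt)


def fx_mul(a: FixedValue, b: FixedValue, events: list | None = None) -> FixedValue:
    """Generic product: floor(a_raw * b_raw / 2^frac), saturating.

    This is the 39x39 -> 39 multiplier with truncation of the low bits.
    """
    _check_fmt(a, b)
    raw = (a.raw * b.raw) >> a.fmt.frac_bits
    return FixedValue(_saturate(raw, a.fmt, events), a.fmt)


def fx_scm_mul(a: FixedValue, plan: ScmPlan, events: list | None = None) -> FixedValue:
    """Multiplierless constant product: sum of sign * (a_raw >> shift).

    Python's ``>>`` on negative integers floors, identical to a hardware
    arithmetic right shift.
    """
    raw = sum(sign * (a.raw >> shift) for sign, shift in plan.terms)
    return FixedValue(_saturate(raw, a.fmt, events), a.fmt)
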