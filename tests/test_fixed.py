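"""Q4.34 arithmetic: quantization semantics and the exact-rational oracle
(every fixed-point operation is checked against Fraction arithmetic)."""

from fractions import Fraction

import pytest

import astroca as ac
from astroca.errors import ValidationError
from astroca.fixed import Q4_34, FixedValue, fx_add, fx_mul, fx_scm_mul, fx_sub, quantize

RES = Fraction(1, 2 ** 34)
RAW_MAX, RAW_MIN = Q4_34.raw_max, Q4_34.raw_min


class TestQuantize:
    def test_representable_round_trip(self):
        fv = quantize(0.5)
        assert fv.raw == 2 ** 33
        assert fv.value == 0.5

    def test_out_of_range_saturates(self):
        assert quantize(20.0).raw == RAW_MAX
        assert quantize(20.0).value == pytest.approx(16 - 2.0 ** -34)
        assert quantize(-20.0).raw == RAW_MIN

    def test_half_ulp_rounds_to_even(self):
        assert quantize(2.0 ** -35).raw == 0
        assert quantize(3 * 2.0 ** -35).raw == 2  # 1.5 ulp -> even raw 2

    def test_error_bounded_by_half_ulp(self):
        for x in (0.1, -1.2345, 3.14159, 15.9):
            assert abs(quantize(x).value - x) <= 2.0 ** -35

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            quantize(float("nan"))


class TestAddSub:
    def test_identity_and_exact_sums(self):
        a = quantize(0.25)
        assert fx_add(a, FixedValue(0)).raw == a.raw
        assert fx_add(quantize(0.25), quantize(0.125)).raw == quantize(0.375).raw

    def test_overflow_saturates(self):
        big = quantize(15.0)
        assert fx_add(big, big).raw == RAW_MAX
        events = []
        fx_add(big, big, events)
        assert len(events) == 1

    def test_format_mismatch_rejected(self):
        other = FixedValue(0, ac.FixedFormat(1, 2, 10))
        with pytest.raises(ValidationError):
            fx_add(quantize(1.0), other)


class TestScmMul:
    def test_single_shift_exact(self):
        plan = ac.scm_decompose(0.5)
        assert fx_scm_mul(quantize(1.0), plan).value == 0.5

    def test_two_shift_exact(self):
        plan = ac.scm_decompose(0.75)
        assert fx_scm_mul(quantize(2.0), plan).value == 1.5

    def test_inexact_constant_within_budget(self):
        plan = ac.scm_decompose(0.018)
        got = fx_scm_mul(quantize(1.0), plan).value
        assert abs(got - 0.018) <= plan.abs_err + len(plan) * 2.0 ** -34


def test_oracle_10k_random_pairs(rng):
    """fx_add / fx_sub / fx_mul / fx_scm_mul against exact rationals."""
    plans = [ac.scm_decompose(c) for c in (0.018, 0.75, -0.3, 7.5, 1.185)]
    raws = rng.integers(RAW_MIN, RAW_MAX + 1, size=(10_000, 2))
    for i, (ra, rb) in enumerate(map(tuple, raws)):
        a, b = FixedValue(int(ra)), FixedValue(int(rb))
        fa, fb = Fraction(int(ra)), Fraction(int(rb))
        assert fx_add(a, b).raw == min(max(fa + fb, RAW_MIN), RAW_MAX)
        assert fx_sub(a, b).raw == min(max(fa - fb, RAW_MIN), RAW_MAX)
        # generic multiply: floor of the exact rational product
        exact = (fa * fb * RES).__floor__()
        assert fx_mul(a, b).raw == min(max(exact, RAW_MIN), RAW_MAX)
        if i % 10 == 0:
            plan = plans[(i // 10) % len(plans)]
            exact = sum(s * (Fraction(int(ra)) / 2 ** k).__floor__()
                        for s, k in plan.terms)
            assert fx_scm_mul(a, plan).raw == min(max(exact, RAW_MIN), RAW_MAX)


def test_split_multiply_identity(rng):
    """The 17/17-bit split used by the numba core equals the big-int product."""
    for ra, rb in rng.integers(RAW_MIN, RAW_MAX + 1, size=(2000, 2)):
        ra, rb = int(ra), int(rb)
        ah, al = ra >> 17, ra & 0x1FFFF
        split = (ah * rb + ((al * rb) >> 17)) >> 17
        assert split == (ra * rb) >> 34
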