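"""PWL approximation tests: interpolation identities, certified error
against an independent dense-grid oracle, and refinement monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import astroca as ac
from astroca.errors import ValidationError

P = ac.AstroParams()

TARGETS = {
    "q2": (lambda x: P.d2 * (x + P.d1) / (x + P.d3), (0.0, 2.0)),
    "m_inf": (lambda x: x / (x + P.d1), (0.0, 2.0)),
    "n_inf": (lambda x: x / (x + P.d5), (0.0, P.ca_max)),
    "hill2": (lambda x: x * x / (P.k_ER ** 2 + x * x), (0.0, P.ca_max)),
}


def brute_force_error(pf, f, n=200_000):
    """Independent max-error estimate on its own dense grid."""
    xs = np.linspace(pf.lo, pf.hi, n)
    return np.max(np.abs(f(xs) - pf(xs)))


def test_affine_function_is_exact_with_one_segment():
    pf = ac.build_pwl(lambda x: 2 * x + 1, (-3.0, 5.0), 1)
    assert pf.max_abs_err == pytest.approx(0.0, abs=1e-12)
    assert pf(0.7) == pytest.approx(2.4)


def test_interpolation_exact_at_breakpoints():
    f, dom = TARGETS["hill2"]
    pf = ac.build_pwl(f, dom, 12, strategy="minimax_greedy")
    assert np.allclose(pf(pf.breakpoints), f(pf.breakpoints), atol=1e-14)


def test_clamping_beyond_domain():
    f, dom = TARGETS["m_inf"]
    pf = ac.build_pwl(f, dom, 8)
    assert pf(dom[1] + 1.0) == pytest.approx(f(dom[1]))
    assert pf(dom[0] - 1.0) == pytest.approx(f(dom[0]))


def test_midpoint_is_mean_of_endpoints_for_linear_samples():
    pf = ac.build_pwl(np.cos, (0.0, 3.0), 6, strategy="uniform")
    bp, nv = pf.breakpoints, pf.node_values
    mid = 0.5 * (bp[2] + bp[3])
    assert pf(mid) == pytest.approx(0.5 * (nv[2] + nv[3]))


@pytest.mark.parametrize("name", sorted(TARGETS))
@pytest.mark.parametrize("strategy", ["uniform", "minimax_greedy"])
def test_refinement_monotonicity(name, strategy):
    f, dom = TARGETS[name]
    errs = [ac.build_pwl(f, dom, n, strategy=strategy).max_abs_err
            for n in (4, 8, 16)]
    assert errs[0] >= errs[1] >= errs[2]


def test_m_inf_cubed_error_certified_against_brute_force():
    f = lambda x: (x / (x + 0.13)) ** 3
    pf16 = ac.build_pwl(f, (0.0, 2.0), 16, strategy="uniform")
    pf4 = ac.build_pwl(f, (0.0, 2.0), 4, strategy="uniform")
    assert pf16.max_abs_err < pf4.max_abs_err
    # the certified bound agrees with an independent dense scan
    assert brute_force_error(pf16, f) <= pf16.max_abs_err * 1.01 + 1e-12


@pytest.mark.parametrize("name", sorted(TARGETS))
def test_build_to_tolerance_is_certified(name):
    f, dom = TARGETS[name]
    pf = ac.build_pwl_to_tol(f, dom, 1e-3, name=name)
    assert pf.max_abs_err <= 1e-3
    assert brute_force_error(pf, f) <= 1.1e-3


def test_json_round_trip():
    f, dom = TARGETS["q2"]
    pf = ac.build_pwl(f, dom, 10)
    clone = ac.PwlFunction.from_dict(pf.to_dict())
    xs = np.linspace(*dom, 777)
    assert np.allclose(pf(xs), clone(xs))


def test_invalid_requests_rejected():
    with pytest.raises(ValidationError):
        ac.build_pwl(np.sin, (1.0, 1.0), 4)
    with pytest.raises(ValidationError):
        ac.build_pwl(np.sin, (0.0, 1.0), 0)
    with pytest.raises(ValidationError):
        ac.build_pwl(lambda x: 1.0 / x, (0.0, 1.0), 4)  # infinite at 0
    with pytest.raises(ValidationError):
        ac.build_pwl(np.sin, (0.0, 1.0), 4, strategy="magic")


@given(coeffs=st.lists(st.floats(-2, 2), min_size=3, max_size=4),
       n_seg=st.integers(2, 12))
@settings(max_examples=40, deadline=None)
def test_pwl_never_extrapolates(coeffs, n_seg):
    """Clamp safety: outputs stay within the sampled node range."""
    f = np.polynomial.Polynomial(coeffs)
    pf = ac.build_pwl(f, (-1.0, 1.0), n_seg, strategy="uniform")
    xs = np.linspace(-5, 5, 301)
    ys = pf(xs)
    assert ys.min() >= pf.node_values.min() - 1e-12
    assert ys.max() <= pf.node_values.max() + 1e-12
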