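"""Single-constant-multiplication (SCM) planning.

A multiplierless digital datapath replaces each multiplication by a model
constant ``c`` with a short sum of arithmetically shifted copies of the
operand: ``c*x ~ sum_i sign_i * (x >> shift_i)``.  Shifts are right shifts
of at most 19 bits, so realizable constants are integer multiples of
2^-19; repeated zero-shifts express the integer part of constants above 1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError

__all__ = ["ScmPlan", "scm_decompose", "exhaustive_scm"]

MAX_SHIFT = 19


@dataclass(frozen=True)
class ScmPlan:
    """A signed shift-add decomposition of a real constant.

    ``terms`` is a tuple of ``(sign, shift)`` with sign in {+1, -1} and
    shift in 0..19; ``realized`` is the value the plan actually computes
    and ``abs_err`` the decomposition error, which is reported, never
    silently dropped.
    """

    target: float
    terms: tuple[tuple[int, int], ...]
    realized: float = field(init=False)
    abs_err: float = field(init=False)

    def __post_init__(self) -> None:
        for sign, shift in self.terms:
            if sign not in (1, -1):
                raise ValidationError(f"invalid SCM sign {sign}")
            if not 0 <= shift <= MAX_SHIFT:
                raise ValidationError(f"SCM shift {shift} outside 0..{MAX_SHIFT}")
        realized = sum(s * 2.0 ** -k for s, k in self.terms)
        object.__setattr__(self, "realized", realized)
        object.__setattr__(self, "abs_err", abs(self.target - realized))

    def __len__(self) -> int:
        return len(self.terms)

    def apply_raw(self, raw: int) -> int:
        """Apply the plan to a raw fixed-point integer (floor shifts)."""
        return sum(s * (raw >> k) for s, k in self.terms)

    def to_dict(self) -> dict:
        return {"target": self.target, "terms": [list(t) for t in self.terms],
                "realized": self.realized, "abs_err": self.abs_err}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ScmPlan":
        return cls(target=d["target"], terms=tuple((s, k) for s, k in d["terms"]))


def scm_decompose(c: float, max_terms: int = 26, max_shift: int = MAX_SHIFT) -> ScmPlan:
    """Greedy signed-digit decomposition of ``c`` over shifts 0..``max_shift``.

    Each step appends the single term minimizing the residual magnitude
    (ties broken towards the larger shift, i.e. the smaller power of two);
    the loop stops when the residual falls below half the shift granule
    2^-(max_shift+1) or the term budget is exhausted.  A zero constant
    yields an empty plan.
    """
    if abs(c) >= 16:
        raise ValidationError("constant magnitude must be below 16 (Q4.34 range)")
    if max_shift > MAX_SHIFT:
        raise ValidationError(f"max_shift cannot exceed {MAX_SHIFT}")
    terms: list[tuple[int, int]] = []
    resid = float(c)
    tol = 2.0 ** -(max_shift + 1)
    while len(terms) < max_terms and abs(resid) > tol:
        best = None
        for shift in range(max_shift + 1):
            for sign in (1, -1):
                err = abs(resid - sign * 2.0 ** -shift)
                # strict < keeps the largest-shift candidate among ties
                if best is None or err < best[0] or (err == best[0] and shift > best[2]):
                    best = (err, sign, shift)
        err, sign, shift = best
        if err >= abs(resid):
            break
        terms.append((sign, shift))
        resid -= sign * 2.0 ** -shift
    return ScmPlan(target=float(c), terms=tuple(terms))


def exhaustive_scm(c: float, max_terms: int = 3, max_shift: int = MAX_SHIFT) -> ScmPlan:
    """Brute-force optimal plan over all signed shift multisets of size
    <= ``max_terms``.  Exponential; intended as a test oracle for small
    budgets only."""
    if max_terms > 4:
        raise ValidationError("exhaustive search is limited to 4 terms")
    best: ScmPlan = ScmPlan(target=float(c), terms=())
    shifts = range(max_shift + 1)
    for k in range(1, max_terms + 1):
        for combo in itertools.combinations_with_replacement(shifts, k):
            for signs in itertools.product((1, -1), repeat=k):
                realized = sum(s * 2.0 ** -sh for s, sh in zip(signs, combo))
                if abs(c - realized) < best.abs_err:
                    best = ScmPlan(target=float(c),
                                   terms=tuple(zip(signs, combo)))
    return best
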