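"""Piecewise-linear (PWL) approximation of the model's scalar nonlinearities.

The digital datapath cannot evaluate rational or Hill functions directly,
so each one is replaced by a continuous chain of line segments that
interpolates the function at the breakpoints.  The certified maximum
absolute error is measured on a dense grid and stored with the design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ValidationError

__all__ = ["PwlFunction", "build_pwl", "build_pwl_to_tol"]


@dataclass(frozen=True)
class PwlFunction:
    """A continuous piecewise-linear interpolant on [lo, hi].

    Evaluation clamps the input to the domain, so the function never
    extrapolates beyond its endpoint values.
    """

    name: str
    lo: float
    hi: float
    breakpoints: np.ndarray   # length n_segments + 1, strictly increasing
    node_values: np.ndarray   # f(breakpoints)
    max_abs_err: float

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, float)
        nv = np.asarray(self.node_values, float)
        if bp.ndim != 1 or len(bp) < 2 or np.any(np.diff(bp) <= 0):
            raise ValidationError("breakpoints must be >= 2 and strictly increasing")
        if len(nv) != len(bp):
            raise ValidationError("node_values length must match breakpoints")
        if not (np.isclose(bp[0], self.lo) and np.isclose(bp[-1], self.hi)):
            raise ValidationError("breakpoints must span [lo, hi]")
        if self.max_abs_err < 0:
            raise ValidationError("max_abs_err must be non-negative")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "node_values", nv)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) - 1

    @property
    def slopes(self) -> np.ndarray:
        return np.diff(self.node_values) / np.diff(self.breakpoints)

    @property
    def intercepts(self) -> np.ndarray:
        """Per-segment intercepts b_k so that y = slope_k * x + b_k."""
        return self.node_values[:-1] - self.slopes * self.breakpoints[:-1]

    def __call__(self, x):
        """Evaluate with clamping; np.interp performs the binary search."""
        out = np.interp(np.asarray(x, float), self.breakpoints, self.node_values)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"name": self.name, "domain": [self.lo, self.hi],
                "breakpoints": self.breakpoints.tolist(),
                "slopes": self.slopes.tolist(),
                "intercepts": self.intercepts.tolist(),
                "node_values": self.node_values.tolist(),
                "max_abs_err": self.max_abs_err}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PwlFunction":
        return cls(name=d["name"], lo=d["domain"][0], hi=d["domain"][1],
                   breakpoints=np.asarray(d["breakpoints"]),
                   node_values=np.asarray(d["node_values"]),
                   max_abs_err=d["max_abs_err"])


def _eval(f: Callable, x) -> np.ndarray:
    """Vectorized, exception-free sampling (division by zero becomes inf)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(f(np.asarray(x, float)), float)


def _certify(f: Callable, bp: np.ndarray, nv: np.ndarray, points_per_seg: int = 1000) -> float:
    """Max |f - PWL| over a dense grid (>= points_per_seg per segment)."""
    grid = np.unique(np.concatenate(
        [np.linspace(bp[i], bp[i + 1], points_per_seg) for i in range(len(bp) - 1)]))
    fx = _eval(f, grid)
    if not np.all(np.isfinite(fx)):
        raise ValidationError("function is not finite on the requested domain")
    return float(np.max(np.abs(fx - np.interp(grid, bp, nv))))


def _seg_err(f: Callable, a: float, b: float, fa: float, fb: float,
             n: int = 200) -> tuple[float, float]:
    """(max error, argmax) of the chord approximation on [a, b]."""
    xs = np.linspace(a, b, n)
    line = fa + (fb - fa) * (xs - a) / (b - a)
    err = np.abs(_eval(f, xs) - line)
    k = int(np.argmax(err))
    return float(err[k]), float(xs[k])


def build_pwl(f: Callable, domain: tuple[float, float], n_segments: int,
              strategy: str = "minimax_greedy", name: str = "") -> PwlFunction:
    """Build an interpolating PWL approximation with ``n_segments`` segments.

    ``uniform`` places breakpoints equidistantly; ``minimax_greedy``
    repeatedly splits the segment with the largest chord error at its
    error maximum, which approximately equidistributes the error.
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not lo < hi:
        raise ValidationError("domain must satisfy lo < hi")
    if n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    if strategy == "uniform":
        bp = np.linspace(lo, hi, n_segments + 1)
    elif strategy == "minimax_greedy":
        bp = [lo, hi]
        v0, v1 = _eval(f, [lo, hi])
        vals = {lo: v0, hi: v1}
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValidationError("function is not finite on the requested domain")
        while len(bp) - 1 < n_segments:
            errs = [_seg_err(f, bp[i], bp[i + 1], vals[bp[i]], vals[bp[i + 1]])
                    for i in range(len(bp) - 1)]
            worst = int(np.argmax([e for e, _ in errs]))
            _, x_split = errs[worst]
            a, b = bp[worst], bp[worst + 1]
            # keep the split strictly interior
            if not a < x_split < b:
                x_split = 0.5 * (a + b)
            bp.insert(worst + 1, x_split)
            vals[x_split] = float(_eval(f, [x_split])[0])
        bp = np.asarray(sorted(bp))
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")
    nv = _eval(f, bp)
    if not np.all(np.isfinite(nv)):
        raise ValidationError("function is not finite on the requested domain")
    err = _certify(f, bp, nv)
    return PwlFunction(name=name or getattr(f, "__name__", "pwl"),
                       lo=lo, hi=hi, breakpoints=bp, node_values=nv,
                       max_abs_err=err)


def build_pwl_to_tol(f: Callable, domain: tuple[float, float], tol: float,
                     max_segments: int = 256, name: str = "") -> PwlFunction:
    """Smallest greedy PWL design whose certified error is <= ``tol``.

    Doubles the greedy budget until the certified (dense-grid) error meets
    the tolerance or ``max_segments`` is reached; in the latter case the
    best design found is returned with its true error recorded.
    """
    n = 1
    best = None
    while n <= max_segments:
        cand = build_pwl(f, domain, n, strategy="minimax_greedy", name=name)
        if best is None or cand.max_abs_err < best.max_abs_err:
            best = cand
        if cand.max_abs_err <= tol:
            return cand
        n *= 2
    return best
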