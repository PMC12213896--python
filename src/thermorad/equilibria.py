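"""Untreated steady states, growth-regime classification and thresholds.

Without treatment the damaged pools stay empty and the vasculature is frozen
at V(0), so the dynamics reduce to a planar system in (T, c).  Two kinds of
steady state arise:

* **space-limited (SL)** — the free volume is exhausted: T* = 1 - V(0) and
  the oxygen balance fixes c* = g*V0 / (q1*(1 - V0) + g*V0); admissible only
  while c* stays at or above the hypoxic threshold c_min;
* **nutrient-limited (NL)** — proliferation balances hypoxic death below the
  threshold.  Writing u = 1 - T - V0 for the free volume, the death balance
  gives c = c_min / (1 + u) and the oxygen balance becomes the quadratic

      c_min*q3 * u**2 + (g*V0 - c_min*((1-V0)*q3 - q1)) * u
          + g*V0*(1-c_min) - c_min*(1-V0)*q1 = 0,

  whose admissible roots (0 < u < 1 - V0) are the NL candidates; stability is
  certified from the eigenvalues of the analytic 2x2 Jacobian.

A parameter triple (q1, q3, V0) is **bistable (BS)** when both a stable NL
point and an admissible SL point coexist.  The sampling thresholds are the
q1 value at which the SL branch crosses c_min and, for fixed q1 below it,
the q3 value above which a stable NL root appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .model_core import ModelParams

__all__ = [
    "FixedPoint",
    "RegimeLabel",
    "NoRootError",
    "sl_fixed_point",
    "nl_candidates",
    "nl_fixed_point",
    "classify_regime",
    "q1_threshold",
    "q3_threshold",
]

_STABILITY_MARGIN = 1e-12
_Q3_BRACKET = (0.01, 10.0)


class RegimeLabel(str, Enum):
    NL = "NL"
    SL = "SL"
    BS = "BS"


class NoRootError(RuntimeError):
    """Raised when a threshold bracket contains no admissibility change."""


@dataclass(frozen=True)
class FixedPoint:
    T_star: float
    c_star: float
    branch: str            # "NL" or "SL"
    stable: bool


def _params(q1: float, q3: float, params: ModelParams | None) -> ModelParams:
    base = params if params is not None else ModelParams()
    return base.for_tumour(q1, q3)


def sl_fixed_point(
    q1: float, q3: float, V0: float, params: ModelParams | None = None
) -> FixedPoint | None:
    """Space-limited steady state, or None if its oxygen level is hypoxic."""
    if not 0 < V0 < 1:
        raise ValueError("V0 must lie in (0, 1)")
    p = _params(q1, q3, params)
    T_star = 1.0 - V0
    c_star = p.g * V0 / (p.q1 * T_star + p.g * V0)
    if c_star < p.c_min:
        return None
    return FixedPoint(T_star=T_star, c_star=c_star, branch="SL", stable=True)


def _nl_quadratic(q1: float, q3: float, V0: float, p: ModelParams):
    a = p.c_min * q3
    b = p.g * V0 - p.c_min * ((1.0 - V0) * q3 - q1)
    c0 = p.g * V0 * (1.0 - p.c_min) - p.c_min * (1.0 - V0) * q1
    return a, b, c0


def _jacobian(T: float, c: float, p: ModelParams, V0: float) -> np.ndarray:
    """Analytic Jacobian of the reduced untreated (T, c) system at c < c_min."""
    q2 = p.q2
    free = 1.0 - T - V0
    j11 = q2 * c * (1.0 - V0 - 2.0 * T) - q2 * (p.c_min - c)
    j12 = q2 * free * T + q2 * T
    j21 = -p.q1 * c - p.q3 * c * (1.0 - V0 - 2.0 * T)
    j22 = -p.g * V0 - p.q1 * T - p.q3 * free * T
    return np.array([[j11, j12], [j21, j22]])


def nl_candidates(
    q1: float, q3: float, V0: float, params: ModelParams | None = None
) -> list[FixedPoint]:
    """All admissible nutrient-limited roots (stable or not)."""
    if not 0 < V0 < 1:
        raise ValueError("V0 must lie in (0, 1)")
    p = _params(q1, q3, params)
    a, b, c0 = _nl_quadratic(q1, q3, V0, p)
    disc = b * b - 4.0 * a * c0
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    out = []
    for u in ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)):
        if not 0.0 < u < 1.0 - V0:
            continue
        T = 1.0 - V0 - u
        c = p.c_min / (1.0 + u)
        eig = np.linalg.eigvals(_jacobian(T, c, p, V0))
        stable = bool(np.max(eig.real) < -_STABILITY_MARGIN)
        out.append(FixedPoint(T_star=T, c_star=c, branch="NL", stable=stable))
    out.sort(key=lambda fp: fp.T_star, reverse=True)
    return out


def nl_fixed_point(
    q1: float, q3: float, V0: float, params: ModelParams | None = None
) -> FixedPoint | None:
    """The stable nutrient-limited steady state, or None if none exists.

    The algebraic system is solved in closed form (the oxygen balance reduces
    to a quadratic in the free volume), so "no root" is decided exactly and a
    root-finder failure mode does not arise.
    """
    for fp in nl_candidates(q1, q3, V0, params):
        if fp.stable:
            return fp
    return None


def classify_regime(
    q1: float, q3: float, V0: float, params: ModelParams | None = None
) -> RegimeLabel:
    """NL, SL or BS depending on which steady states are admissible.

    Exact threshold ties go to the open side of the sampling intervals: a
    tumour with the SL branch exactly at c* = c_min counts as NL.
    """
    p = _params(q1, q3, params)
    sl = sl_fixed_point(q1, q3, V0, p)
    sl_ok = sl is not None and sl.c_star > p.c_min
    nl_ok = nl_fixed_point(q1, q3, V0, p) is not None
    if sl_ok and nl_ok:
        return RegimeLabel.BS
    if sl_ok:
        return RegimeLabel.SL
    if nl_ok:
        return RegimeLabel.NL
    raise ValueError(
        f"no admissible steady state for (q1={q1}, q3={q3}, V0={V0})"
    )


def q1_threshold(V0: float, params: ModelParams | None = None) -> float:
    """q1 value at which the SL branch's oxygen level crosses c_min.

    Below the threshold an SL steady state exists.  Located numerically on
    the SL oxygen balance; the closed form
    g*V0*(1 - c_min) / ((1 - V0)*c_min) serves as an independent oracle in
    the test-suite.
    """
    if not 0 < V0 < 1:
        raise ValueError("V0 must lie in (0, 1)")
    p = params if params is not None else ModelParams()

    def gap(q1: float) -> float:
        c_star = p.g * V0 / (q1 * (1.0 - V0) + p.g * V0)
        return c_star - p.c_min

    lo, hi = 1e-12, 1.0
    while gap(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - c_min in (0,1) guarantees a root
            raise NoRootError("SL admissibility does not cross c_min")
    return float(brentq(gap, lo, hi, xtol=1e-14, rtol=1e-15))


def q3_threshold(
    V0: float, q1: float, params: ModelParams | None = None
) -> float:
    """q3 value above which a stable NL root coexists with the SL state.

    Requires q1 at or below the q1 threshold; located by bisection on NL-root
    existence over the sampling box q3 in [0.01, 10].
    """
    p = params if params is not None else ModelParams()
    if q1 > q1_threshold(V0, p) * (1.0 + 1e-12):
        raise ValueError("q3 threshold is defined only for q1 <= q1_threshold")

    def has_nl(q3: float) -> bool:
        return nl_fixed_point(q1, q3, V0, p) is not None

    lo, hi = _Q3_BRACKET
    if has_nl(lo) or not has_nl(hi):
        raise NoRootError(
            f"no NL-existence change in q3 bracket {_Q3_BRACKET} "
            f"for (V0={V0}, q1={q1})"
        )
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if has_nl(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
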