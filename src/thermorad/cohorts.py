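"""Seeded virtual tumour populations for the three growth regimes.

Each cohort fixes its vascular volume (NL: 0.0005, SL: 0.005, BS: 0.00275)
and draws (q1, q3) pairs from regime-specific uniform boxes bounded by the
sampling thresholds:

* NL: q1 ~ U(q1_bar, 10),  q3 ~ U(0.01, 10)
* SL: q1 ~ U(0.01, q1_bar), q3 ~ U(0.01, q3_bar(q1))
* BS: q1 ~ U(0.01, q1_bar), q3 ~ U(q3_bar(q1), 10)

q3_bar depends on q1, so q1 is drawn first.  For low-q1 SL draws no NL root
exists anywhere in the box and q3_bar is undefined; the upper bound then
falls back to the box edge (10).  Because the thresholds are computed
numerically, each draw is verified with the classifier and the rare
misclassified pair is redrawn.  Every tumour carries its own RNG sub-stream
keyed by (cohort seed, tumour id), so cohorts are extensible without
reshuffling existing members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import (
    NoRootError,
    RegimeLabel,
    classify_regime,
    nl_fixed_point,
    q1_threshold,
    q3_threshold,
    sl_fixed_point,
)
from .model_core import ModelParams, State

__all__ = [
    "COHORT_V0",
    "VirtualTumour",
    "Cohort",
    "sample_cohort",
    "baseline_state",
    "cohort_to_frame",
    "cohort_from_frame",
]

#: Cohort-specific vascular volumes.
COHORT_V0 = {
    RegimeLabel.NL: 0.0005,
    RegimeLabel.SL: 0.005,
    RegimeLabel.BS: 0.00275,
}

_BOX = (0.01, 10.0)          # global (q1, q3) sampling box
_MAX_REJECT_FRACTION = 0.2   # more rejections than this signals a fault


@dataclass(frozen=True)
class VirtualTumour:
    """A sampled (q1, q3, V0) triple with its regime and baseline state."""

    id: int
    q1: float
    q3: float
    V0: float
    regime: RegimeLabel
    T_star: float
    c_star: float

    def params(self, base: ModelParams | None = None) -> ModelParams:
        return (base or ModelParams()).for_tumour(self.q1, self.q3)


@dataclass(frozen=True)
class Cohort:
    regime: RegimeLabel
    tumours: tuple[VirtualTumour, ...]
    seed: int
    N: int

    @property
    def V0(self) -> float:
        return COHORT_V0[self.regime]


def _resolve_baseline(
    q1: float, q3: float, V0: float, regime: RegimeLabel, params: ModelParams
) -> tuple[float, float]:
    """Baseline (T*, c*): the NL branch for NL/BS tumours, SL branch for SL."""
    if regime is RegimeLabel.SL:
        fp = sl_fixed_point(q1, q3, V0, params)
    else:
        fp = nl_fixed_point(q1, q3, V0, params)
    if fp is None:  # pragma: no cover - classification guarantees existence
        raise RuntimeError("baseline fixed point vanished after classification")
    return fp.T_star, fp.c_star


def _q3_bounds(
    regime: RegimeLabel, q1: float, V0: float, params: ModelParams
) -> tuple[float, float]:
    if regime is RegimeLabel.NL:
        return _BOX
    try:
        q3_bar = q3_threshold(V0, q1, params)
    except NoRootError:
        if regime is RegimeLabel.BS:
            raise
        return _BOX  # SL: no NL root anywhere in the box
    if regime is RegimeLabel.SL:
        return (_BOX[0], q3_bar)
    return (q3_bar, _BOX[1])


def sample_cohort(
    regime: RegimeLabel,
    N: int = 250,
    seed: int = 0,
    params: ModelParams | None = None,
) -> Cohort:
    """Draw a seeded cohort of N virtual tumours of the requested regime."""
    regime = RegimeLabel(regime)
    p = params if params is not None else ModelParams()
    V0 = COHORT_V0[regime]
    q1_bar = q1_threshold(V0, p)
    q1_bounds = (q1_bar, _BOX[1]) if regime is RegimeLabel.NL \
        else (_BOX[0], q1_bar)

    tumours = []
    rejected = 0
    for i in range(N):
        rng = np.random.default_rng([seed, i])
        while True:
            q1 = rng.uniform(*q1_bounds)
            q3 = rng.uniform(*_q3_bounds(regime, q1, V0, p))
            if classify_regime(q1, q3, V0, p) is regime:
                break
            rejected += 1
            if rejected > _MAX_REJECT_FRACTION * max(N, 10):
                raise RuntimeError(
                    f"rejection rate above {_MAX_REJECT_FRACTION:.0%} while "
                    f"sampling the {regime.value} cohort; threshold "
                    "computation is likely faulty"
                )
        T_star, c_star = _resolve_baseline(q1, q3, V0, regime, p)
        tumours.append(
            VirtualTumour(
                id=i, q1=q1, q3=q3, V0=V0, regime=regime,
                T_star=T_star, c_star=c_star,
            )
        )
    return Cohort(regime=regime, tumours=tuple(tumours), seed=seed, N=N)


def baseline_state(tumour: VirtualTumour) -> State:
    """Pre-treatment state: damage pools empty, (T, c) at the untreated
    steady state (the NL branch for BS tumours) and repair proteins active."""
    return State(
        T=tumour.T_star, T_S=0.0, T_R=0.0, T_H=0.0,
        V=tumour.V0, c=tumour.c_star, Lambda=0.0,
    )


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write the cohort CSV with shortest round-trippable floats."""
    cohort_to_frame(cohort).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def read_cohort_csv(path, seed: int = -1) -> Cohort:
    """Exact-precision counterpart of :func:`write_cohort_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return cohort_from_frame(df, seed=seed)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [t.id for t in cohort.tumours],
            "regime": [t.regime.value for t in cohort.tumours],
            "q1": [t.q1 for t in cohort.tumours],
            "q3": [t.q3 for t in cohort.tumours],
            "V0": [t.V0 for t in cohort.tumours],
            "T_star": [t.T_star for t in cohort.tumours],
            "c_star": [t.c_star for t in cohort.tumours],
        }
    )


def cohort_from_frame(df: pd.DataFrame, seed: int = -1) -> Cohort:
    """Rebuild a cohort from its CSV representation (seed optional)."""
    tumours = tuple(
        VirtualTumour(
            id=int(row.id), q1=float(row.q1), q3=float(row.q3),
            V0=float(row.V0), regime=RegimeLabel(row.regime),
            T_star=float(row.T_star), c_star=float(row.c_star),
        )
        for row in df.itertuples()
    )
    regimes = {t.regime for t in tumours}
    if len(regimes) != 1:
        raise ValueError("cohort frame mixes regimes")
    return Cohort(
        regime=tumours[0].regime, tumours=tumours, seed=seed, N=len(tumours)
    )
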