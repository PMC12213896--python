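"""End-of-treatment response metrics, stratification and deleterious flag.

The four percent-change metrics compare last-week means against the
pre-treatment steady state:

    delta_viable = 100 * ((T_bar + TS_bar) - T*) / T*
    delta_total  = 100 * (Sigma_bar - Sigma_0) / Sigma_0,  Sigma_0 = T* + V0
    delta_V      = 100 * (V_bar - V0) / V0
    delta_c      = 100 * (c_bar - c*) / c*

The scalar efficacy measure is the combined score delta_viable + delta_total
(large negative = effective).  Within one (cohort, schedule) pair, tumours
with a negative combined score are stratified into four classes at the 10%,
37.5% and 62.5% percentiles of the score distribution; non-negative scores
form the fifth, "negative-response" class.  A treatment is deleterious when
max(combined score, delta_V) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .cohorts import VirtualTumour
from .simulate import LastWeekMeans

__all__ = [
    "ResponseClass",
    "ResponseSummary",
    "percent_changes",
    "stratify_cohort",
    "is_deleterious",
]


_ZERO_SNAP = 1e-9  # percentage points


class ResponseClass(str, Enum):
    NEGATIVE = "negative"
    LIMITED = "limited"
    MODERATE = "moderate"
    POSITIVE = "positive"
    STRONGLY_POSITIVE = "strongly_positive"


@dataclass
class ResponseSummary:
    """Metrics for one (tumour, schedule, treatment) simulation."""

    delta_viable: float
    delta_total: float
    delta_V: float
    delta_c: float
    treatment: str = ""                       # "R", "H" or "R_H"
    response_class: ResponseClass | None = None

    @property
    def combined_score(self) -> float:
        return self.delta_viable + self.delta_total

    @property
    def deleterious(self) -> bool:
        return is_deleterious(self)


def percent_changes(
    means: LastWeekMeans, tumour: VirtualTumour, treatment: str = ""
) -> ResponseSummary:
    """The four percent-change metrics for one simulated treatment."""
    T_star, V0, c_star = tumour.T_star, tumour.V0, tumour.c_star
    if T_star <= 0 or V0 <= 0 or c_star <= 0:
        raise ValueError("baseline volumes and oxygen must be positive")
    sigma0 = T_star + V0

    def pct(value: float, base: float) -> float:
        d = 100.0 * (value - base) / base
        # Strict sign rules (deleterious/ineffective flags) must not trip on
        # integrator round-off; an untreated pool is unchanged by definition.
        return 0.0 if abs(d) < _ZERO_SNAP else d

    return ResponseSummary(
        delta_viable=pct(means.T_bar + means.TS_bar, T_star),
        delta_total=pct(means.sigma_bar, sigma0),
        delta_V=pct(means.V_bar, V0),
        delta_c=pct(means.c_bar, c_star),
        treatment=treatment,
    )


def is_deleterious(summary: ResponseSummary) -> bool:
    """True when max(combined score, delta_V) is strictly positive."""
    return max(summary.combined_score, summary.delta_V) > 0.0


def stratify_cohort(
    scores: Sequence[float], include_nonnegative: bool = False
) -> list[ResponseClass]:
    """Five-class stratification of combined scores for one cohort/schedule.

    Percentiles (linear interpolation between order statistics) are computed
    over the negative-score subset by default, matching stratification
    intervals that terminate at 0; ``include_nonnegative=True`` computes them
    over all scores instead.  Scores >= 0 are always classed "negative".
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return []
    pool = scores if include_nonnegative else scores[scores < 0]
    if pool.size == 0:
        return [ResponseClass.NEGATIVE] * scores.size
    if pool.size < 10:
        import warnings

        warnings.warn(
            f"percentile estimates from only {pool.size} scores are unstable",
            stacklevel=2,
        )
    q10, q375, q625 = np.percentile(pool, [10.0, 37.5, 62.5])

    def classify(s: float) -> ResponseClass:
        if s >= 0:
            return ResponseClass.NEGATIVE
        if s < q10:
            return ResponseClass.STRONGLY_POSITIVE
        if s < q375:
            return ResponseClass.POSITIVE
        if s < q625:
            return ResponseClass.MODERATE
        return ResponseClass.LIMITED

    return [classify(s) for s in scores]
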