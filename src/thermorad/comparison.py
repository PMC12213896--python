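"""Rule-based comparison of RT, HT and combined treatment, and ranking.

Three rules drive the per-tumour comparison for a matched pair of RT and HT
dosing protocols:

1. a treatment is *ineffective* (excluded) if any of delta_viable,
   delta_total, delta_V is strictly positive;
2. combined treatment beats a monotherapy only if it improves both the
   viable and total reductions by at least 10 percentage points **and**
   strictly improves the vascular reduction;
3. between the monotherapies, HT wins iff its combined score is strictly
   smaller than RT's (ties go to RT).

The two-step regimen ranking first picks the best treatment for every
schedule pair, then orders the winners by combined score (ascending); a
combined-treatment entry that fails the Rule-2 margin against its matched
monotherapy is demoted in favour of that monotherapy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .response_metrics import ResponseSummary

__all__ = [
    "RULE2_MARGIN",
    "MatchedTriple",
    "RankedOutcome",
    "rule1_ineffective",
    "rule2_combined_better",
    "rule3_ht_better",
    "best_treatment",
    "rank_regimens",
]

RULE2_MARGIN = -10.0  # percentage points

#: Deterministic tie order for equal scores.
_TREATMENT_ORDER = {"R": 0, "H": 1, "R_H": 2}

Rule2Mode = Literal["better", "both"]


@dataclass(frozen=True)
class MatchedTriple:
    """RT, HT and combined summaries for one matched schedule pair."""

    tumour_id: int
    rt: ResponseSummary
    ht: ResponseSummary
    combo: ResponseSummary
    schedule_pair: tuple[str, str] = ("", "")


@dataclass
class RankedOutcome:
    tumour_id: int
    best_treatment: str                     # "R", "H", "R_H" or "none_effective"
    best_regimen: str = ""
    ranking: list[tuple[str, str, float]] = field(default_factory=list)


def rule1_ineffective(summary: ResponseSummary) -> bool:
    """Exclusion rule: any individual metric strictly positive."""
    return max(summary.delta_viable, summary.delta_total, summary.delta_V) > 0.0


def rule2_combined_better(combo: ResponseSummary, mono: ResponseSummary) -> bool:
    """Combined beats a monotherapy: >=10-point viable and total margins and
    a strictly better vascular reduction."""
    margin_ok = (
        max(
            combo.delta_viable - mono.delta_viable,
            combo.delta_total - mono.delta_total,
        )
        <= RULE2_MARGIN
    )
    return margin_ok and combo.delta_V < mono.delta_V


def rule3_ht_better(ht: ResponseSummary, rt: ResponseSummary) -> bool:
    """HT beats RT iff its combined score is strictly smaller."""
    return ht.combined_score < rt.combined_score


def best_treatment(
    triple: MatchedTriple, rule2_mode: Rule2Mode = "better"
) -> str:
    """Most effective of R / H / R_H for one matched schedule pair.

    ``rule2_mode`` selects whether combined treatment must beat only the
    better surviving monotherapy ("better", default) or every surviving
    monotherapy ("both").
    """
    survivors = {
        name: s
        for name, s in (
            ("R", triple.rt), ("H", triple.ht), ("R_H", triple.combo)
        )
        if not rule1_ineffective(s)
    }
    best_mono = None
    if "R" in survivors and "H" in survivors:
        best_mono = "H" if rule3_ht_better(triple.ht, triple.rt) else "R"
    elif "R" in survivors:
        best_mono = "R"
    elif "H" in survivors:
        best_mono = "H"

    if "R_H" in survivors:
        if best_mono is None:
            return "R_H"
        if rule2_mode == "better":
            targets = [survivors[best_mono]]
        else:
            targets = [survivors[m] for m in ("R", "H") if m in survivors]
        if all(rule2_combined_better(triple.combo, m) for m in targets):
            return "R_H"
    if best_mono is not None:
        return best_mono
    return "none_effective"


def _summary_for(triple: MatchedTriple, treatment: str) -> ResponseSummary:
    return {"R": triple.rt, "H": triple.ht, "R_H": triple.combo}[treatment]


def _regimen_descriptor(triple: MatchedTriple, treatment: str) -> str:
    rt_desc, ht_desc = triple.schedule_pair
    if treatment == "R":
        return rt_desc
    if treatment == "H":
        return ht_desc
    return f"{rt_desc}+{ht_desc}"


def rank_regimens(
    triples: Sequence[MatchedTriple], rule2_mode: Rule2Mode = "better"
) -> RankedOutcome:
    """Two-step ranking of all schedule pairs for one tumour."""
    if not triples:
        raise ValueError("rank_regimens requires at least one matched triple")
    tumour_id = triples[0].tumour_id
    if any(t.tumour_id != tumour_id for t in triples):
        raise ValueError("all matched triples must belong to one tumour")

    entries = []
    for triple in triples:
        winner = best_treatment(triple, rule2_mode)
        if winner == "none_effective":
            continue
        # Demote a combined winner whose Rule-2 margin fails against its own
        # matched monotherapies (defensive: best_treatment already enforces
        # it for the mode's target set).
        if winner == "R_H":
            monos = {
                m: _summary_for(triple, m)
                for m in ("R", "H")
                if not rule1_ineffective(_summary_for(triple, m))
            }
            if rule2_mode == "better" and len(monos) == 2:
                keep = "H" if rule3_ht_better(triple.ht, triple.rt) else "R"
                monos = {keep: monos[keep]}
            failing = [
                m for m, s in monos.items()
                if not rule2_combined_better(triple.combo, s)
            ]
            if failing:
                if len(monos) == 2:
                    winner = (
                        "H" if rule3_ht_better(triple.ht, triple.rt) else "R"
                    )
                else:
                    winner = next(iter(monos))
        summary = _summary_for(triple, winner)
        entries.append(
            (winner, _regimen_descriptor(triple, winner), summary.combined_score)
        )

    if not entries:
        return RankedOutcome(tumour_id=tumour_id, best_treatment="none_effective")

    entries.sort(key=lambda e: (e[2], _TREATMENT_ORDER[e[0]], e[1]))
    best = entries[0]
    return RankedOutcome(
        tumour_id=tumour_id,
        best_treatment=best[0],
        best_regimen=best[1],
        ranking=entries,
    )
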