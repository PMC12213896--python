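"""Construction of RT, HT and combined treatment plans on a minute clock.

Conventions: t = 0 is Monday at the daily treatment time; a week is 10080
minutes and a day 1440.  RT fractions last 10 min and repeat at the same time
each day — five fractions run Monday–Friday, three run Monday/Wednesday/
Friday, one runs Monday.  HT fractions last 60 min and are given once a week
on Mondays; under combined treatment the HT fraction starts one minute after
that Monday's RT fraction ends.

Two maximum-tolerated-dose caps apply: 80 Gy of total radiation (the number
of treatment weeks is chosen so the total dose is as close as possible to
80 Gy) and a total thermal dose beta_tilde * N_wks of at most 0.08.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Modality",
    "Schedule",
    "MINUTES_PER_DAY",
    "MINUTES_PER_WEEK",
    "D_MAX",
    "BETA_MAX",
    "DELTA_R",
    "DELTA_H",
    "rt_weeks",
    "build_rt_schedule",
    "build_ht_schedule",
    "build_combined",
    "null_schedule",
    "conventional_rt",
    "conventional_ht",
    "conventional_combined",
    "event_times",
]

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY  # 10080

D_MAX = 80.0      # Gy, total radiation MTD
BETA_MAX = 0.08   # cap on beta_tilde * N_wks
DELTA_R = 10.0    # min, RT fraction duration
DELTA_H = 60.0    # min, HT fraction duration
HT_DELAY = 1.0    # min between end of Monday RT fraction and start of HT

_VALID_N_FRAC = (1, 3, 5)
#: Fraction-day offsets (in days from Monday) for each weekly fraction count.
_FRACTION_DAYS = {1: (0,), 3: (0, 2, 4), 5: (0, 1, 2, 3, 4)}


class Modality(str, Enum):
    RT = "RT"
    HT = "HT"
    RT_HT = "RT_HT"
    NONE = "NONE"


@dataclass(frozen=True)
class Schedule:
    """A fully resolved treatment plan with explicit minute windows."""

    modality: Modality
    D: float = 0.0                 # Gy per RT fraction
    N_frac: int = 0                # RT fractions per week
    delta_R: float = DELTA_R
    beta_tilde: float = 0.0        # HT damage rate during a fraction
    delta_H: float = DELTA_H
    N_wks: int = 0
    rt_windows: tuple[tuple[float, float], ...] = ()
    ht_windows: tuple[tuple[float, float], ...] = ()

    @property
    def t_end(self) -> float:
        return self.N_wks * MINUTES_PER_WEEK

    @property
    def total_rt_dose(self) -> float:
        return self.D * self.N_frac * self.N_wks

    @property
    def total_thermal_dose(self) -> float:
        return self.beta_tilde * self.N_wks

    def describe(self) -> str:
        """Short descriptor used in output tables, e.g. ``RT:D2xF5xW8``."""
        parts = [self.modality.value]
        if self.modality in (Modality.RT, Modality.RT_HT):
            parts.append(f"D{self.D:g}xF{self.N_frac}")
        if self.modality in (Modality.HT, Modality.RT_HT):
            parts.append(f"b{self.beta_tilde:g}")
        parts.append(f"W{self.N_wks}")
        return ":".join(parts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "modality": self.modality.value,
                "D": self.D,
                "N_frac": self.N_frac,
                "delta_R": self.delta_R,
                "beta_tilde": self.beta_tilde,
                "delta_H": self.delta_H,
                "N_wks": self.N_wks,
                "t_end": self.t_end,
                "rt_windows": [list(w) for w in self.rt_windows],
                "ht_windows": [list(w) for w in self.ht_windows],
            },
            indent=2,
        )


def rt_weeks(D: float, N_frac: int) -> int:
    """Number of treatment weeks bringing the total dose closest to 80 Gy.

    Ties are broken toward fewer weeks (the lower total dose).
    """
    weekly = D * N_frac
    if weekly <= 0:
        raise ValueError("weekly dose must be positive")
    best, best_err = 1, abs(weekly - D_MAX)
    n = 1
    while True:
        n += 1
        err = abs(weekly * n - D_MAX)
        if err < best_err:
            best, best_err = n, err
        if weekly * n > 2 * D_MAX:  # error grows monotonically from here
            break
    return best


def _rt_windows(D: float, N_frac: int, N_wks: int) -> tuple[tuple[float, float], ...]:
    windows = []
    for week in range(N_wks):
        monday = week * MINUTES_PER_WEEK
        for day in _FRACTION_DAYS[N_frac]:
            start = monday + day * MINUTES_PER_DAY
            windows.append((start, start + DELTA_R))
    return tuple(windows)


def _ht_windows(N_wks: int, start_offset: float) -> tuple[tuple[float, float], ...]:
    return tuple(
        (week * MINUTES_PER_WEEK + start_offset,
         week * MINUTES_PER_WEEK + start_offset + DELTA_H)
        for week in range(N_wks)
    )


def _check_rt_args(D: float, N_frac: int) -> None:
    if N_frac not in _VALID_N_FRAC:
        raise ValueError(f"N_frac must be one of {_VALID_N_FRAC}, got {N_frac}")
    if not 1 <= D <= 5:
        raise ValueError(f"RT fraction dose must lie in [1, 5] Gy, got {D}")


def build_rt_schedule(D: float, N_frac: int) -> Schedule:
    """RT-only plan: weekly Monday-anchored fractions, weeks set by the MTD."""
    _check_rt_args(D, N_frac)
    N_wks = rt_weeks(D, N_frac)
    return Schedule(
        modality=Modality.RT,
        D=float(D),
        N_frac=N_frac,
        N_wks=N_wks,
        rt_windows=_rt_windows(D, N_frac, N_wks),
    )


def build_ht_schedule(beta_tilde: float, N_wks: int) -> Schedule:
    """HT-only plan: one 60-min Monday fraction per week."""
    if beta_tilde <= 0:
        raise ValueError("beta_tilde must be positive")
    if N_wks < 1:
        raise ValueError("N_wks must be at least 1")
    total = beta_tilde * N_wks
    if total > BETA_MAX + 1e-12:
        raise ValueError(
            f"thermal MTD violated: beta_tilde*N_wks = {total:g} > {BETA_MAX}"
        )
    return Schedule(
        modality=Modality.HT,
        beta_tilde=float(beta_tilde),
        N_wks=int(N_wks),
        ht_windows=_ht_windows(N_wks, 0.0),
    )


def build_combined(D: float, N_frac: int, beta_tilde: float) -> Schedule:
    """Combined plan: RT as in the RT-only plan, plus Monday HT fractions.

    The HT fraction starts one minute after the Monday RT fraction ends;
    the number of weeks is inherited from the RT MTD rule.
    """
    if beta_tilde == 0:
        return build_rt_schedule(D, N_frac)
    _check_rt_args(D, N_frac)
    if beta_tilde < 0:
        raise ValueError("beta_tilde must be non-negative")
    N_wks = rt_weeks(D, N_frac)
    total = beta_tilde * N_wks
    if total > BETA_MAX + 1e-12:
        raise ValueError(
            f"thermal MTD violated: beta_tilde*N_wks = {total:g} > {BETA_MAX}"
        )
    return Schedule(
        modality=Modality.RT_HT,
        D=float(D),
        N_frac=N_frac,
        beta_tilde=float(beta_tilde),
        N_wks=N_wks,
        rt_windows=_rt_windows(D, N_frac, N_wks),
        ht_windows=_ht_windows(N_wks, DELTA_R + HT_DELAY),
    )


def null_schedule(N_wks: int = 8) -> Schedule:
    """No-treatment plan over the given horizon (used for equilibrium checks)."""
    return Schedule(modality=Modality.NONE, N_wks=int(N_wks))


def conventional_rt() -> Schedule:
    """The reference RT plan: 5 x 2 Gy per week for 8 weeks (80 Gy)."""
    return build_rt_schedule(2.0, 5)


def conventional_ht() -> Schedule:
    """The reference HT plan: beta_tilde = 0.005 weekly for 8 weeks."""
    return build_ht_schedule(0.005, 8)


def conventional_combined() -> Schedule:
    """The reference combined plan (conventional RT + conventional HT)."""
    return build_combined(2.0, 5, 0.005)


def event_times(schedule: Schedule) -> list[float]:
    """Sorted, de-duplicated breakpoints: window edges plus 0 and t_end."""
    pts = {0.0, schedule.t_end}
    for start, end in schedule.rt_windows:
        pts.update((start, end))
    for start, end in schedule.ht_windows:
        pts.update((start, end))
    return sorted(pts)
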