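"""Dimensionless tumour-vasculature-oxygen model with treatment forcing.

The state has seven components: undamaged tumour volume ``T``, sub-lethally
radiation-damaged volume ``T_S``, lethally radiation-damaged volume ``T_R``,
lethally heat-damaged volume ``T_H``, vascular volume ``V``, oxygen
concentration ``c`` and the inactive repair-protein fraction ``Lambda``.
Volumes are fractions of the total available volume, oxygen is scaled by its
vascular value, and time is measured in minutes.

Radiotherapy (RT) enters through a piecewise-constant dose rate and
hyperthermia (HT) through a piecewise-constant damage rate; both are read off
a resolved :class:`~thermorad.schedules.Schedule`.  HT additionally
inactivates DNA-repair proteins, which suppresses the repair rate of
sub-lethally damaged cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "STATE_NAMES",
    "heaviside",
    "rt_dose_rate",
    "ht_damage_rate",
    "lambda_closed_form",
    "repair_rate",
    "rhs",
    "rhs_autonomous",
]

#: Order of the augmented state vector.
STATE_NAMES = ("T", "T_S", "T_R", "T_H", "V", "c", "Lambda")

# Parameter names that may appear in a serialised mapping.  Derived values
# (q2, delta, delta_S, k1) are always recomputed, never read from file.
_SERIALISABLE = (
    "c_min", "g", "k", "q1", "q3", "theta1", "theta2",
    "nu", "lam", "lam_S", "mu0", "xi", "eta_R",
    "kappa0", "eta_H", "mu_Lambda", "k2",
)


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless rate constants of the growth/RT/HT model.

    Defaults are the reference values used throughout the virtual-trial
    analysis; ``q1`` and ``q3`` are tumour-specific and ``k1`` is tied to the
    HT dose of the active schedule (``k1 = 100 * beta_tilde``).
    """

    # growth
    c_min: float = 1e-2        # hypoxic (anoxic) oxygen threshold
    g: float = 5.0             # oxygen exchange rate per unit vascular volume
    k: float = 1e-2            # conversion factor linking q2 and q3
    q1: float = 1.0            # O2 consumption rate for maintenance
    q3: float = 1.0            # O2 consumption rate for proliferation
    theta1: float = 10.0       # maintenance-consumption multiplier (damaged)
    theta2: float = 0.1        # proliferation multiplier (damaged)
    # RT response
    nu: float = 10.0           # sub-lethal damage rate
    lam: float = 1.0           # lethal damage rate, undamaged cells
    lam_S: float = 1.0         # lethal damage rate, sub-lethally damaged cells
    mu0: float = 5e-3          # baseline repair rate
    xi: float = 5e-4           # mitotic-catastrophe rate
    eta_R: float = 5e-5        # clearance of RT-killed cells
    # HT response
    kappa0: float = 1e-7       # damage-induced angiogenesis rate
    eta_H: float = 5e-5        # clearance of HT-killed cells
    mu_Lambda: float = 2.5     # repair-inhibition weight
    k1: float = 0.0            # repair-protein inactivation rate (100*beta)
    k2: float = 1e-3           # repair-protein reactivation rate

    # ---- derived quantities -------------------------------------------------
    @property
    def q2(self) -> float:
        """Proliferation rate; fixed by the conversion factor, q2 = k*q3."""
        return self.k * self.q3

    @property
    def delta(self) -> float:
        """Hypoxic death rate of undamaged cells (= q2)."""
        return self.q2

    @property
    def delta_S(self) -> float:
        """Hypoxic death rate of sub-lethally damaged cells (= theta2*q2)."""
        return self.theta2 * self.q2

    # ---- construction helpers ----------------------------------------------
    def for_tumour(self, q1: float, q3: float) -> "ModelParams":
        """Return a copy with tumour-specific oxygen consumption rates."""
        return replace(self, q1=float(q1), q3=float(q3))

    def with_beta(self, beta_tilde: float) -> "ModelParams":
        """Return a copy with the repair-inactivation rate k1 = 100*beta.

        RT-only schedules (beta_tilde == 0) get k1 = 0 so Lambda stays 0 and
        the repair rate stays at mu0.
        """
        return replace(self, k1=100.0 * float(beta_tilde))

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v!r} must be finite and >= 0")
        if not 0 < self.c_min < 1:
            raise ValueError("c_min must lie in (0, 1)")
        if not 0 < self.theta2 < 1:
            raise ValueError("theta2 must lie in (0, 1)")
        if self.theta1 <= 1:
            raise ValueError("theta1 must exceed 1")

    # ---- serialisation ------------------------------------------------------
    def to_mapping(self) -> dict[str, float]:
        """Flat mapping of the free parameters (derived fields excluded)."""
        return {name: float(getattr(self, name)) for name in _SERIALISABLE}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParams":
        unknown = set(mapping) - set(_SERIALISABLE)
        if unknown:
            raise ValueError(
                f"unknown or derived parameter(s) in mapping: {sorted(unknown)}"
            )
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass
class State:
    """One point of the augmented state, plus the total-volume readout."""

    T: float
    T_S: float
    T_R: float
    T_H: float
    V: float
    c: float
    Lambda: float = 0.0

    @property
    def sigma(self) -> float:
        return self.T + self.T_S + self.T_R + self.T_H + self.V

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.T, self.T_S, self.T_R, self.T_H, self.V, self.c, self.Lambda]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        return cls(*(float(v) for v in y))


def heaviside(x: float) -> int:
    """Unit step: 1 for x >= 0, 0 for x < 0."""
    if not math.isfinite(x):
        raise ValueError(f"heaviside requires a finite argument, got {x!r}")
    return 1 if x >= 0 else 0


def rt_dose_rate(t: float, schedule) -> float:
    """Dimensionless RT dose rate at time ``t`` (D/delta_R inside a window)."""
    if schedule.D == 0 or not schedule.rt_windows:
        return 0.0
    for start, end in schedule.rt_windows:
        if start <= t <= end:
            return schedule.D / schedule.delta_R
    return 0.0


def ht_damage_rate(t: float, schedule) -> float:
    """HT damage rate at time ``t`` (beta_tilde inside a window, else 0)."""
    if schedule.beta_tilde == 0 or not schedule.ht_windows:
        return 0.0
    for start, end in schedule.ht_windows:
        if start <= t <= end:
            return schedule.beta_tilde
    return 0.0


def lambda_closed_form(
    t: float, t_H: float, delta_H: float, k1: float, k2: float
) -> float:
    """Inactive repair-protein fraction after a single HT fraction.

    Zero before the fraction, saturating growth at rate (k1 + k2) during it,
    exponential decay at rate k2 afterwards; continuous at both endpoints.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    if t < t_H:
        return 0.0
    ks = k1 + k2
    if t < t_H + delta_H:
        return (k1 / ks) * (1.0 - math.exp(-ks * (t - t_H)))
    peak = (k1 / ks) * (1.0 - math.exp(-ks * delta_H))
    return peak * math.exp(-k2 * (t - (t_H + delta_H)))


def repair_rate(Lambda: float, mu0: float, mu_Lambda: float) -> float:
    """Heat-suppressed repair rate mu0 * exp(-mu_Lambda * Lambda)."""
    if not 0.0 <= Lambda <= 1.0:
        raise ValueError(f"Lambda must lie in [0, 1], got {Lambda!r}")
    return mu0 * math.exp(-mu_Lambda * Lambda)


def rhs_autonomous(
    y, p: ModelParams, R: float, beta: float, ht_on: bool
) -> np.ndarray:
    """Time-derivative of the augmented state under constant forcing.

    ``R`` is the RT dose rate, ``beta`` the HT damage rate and ``ht_on``
    flags whether repair-protein inactivation is currently driven (it is
    active exactly during HT windows).  Within one treatment segment the
    forcing is constant, so this form is what the integrator sees.
    """
    T, T_S, T_R, T_H, V, c, Lam = y
    sigma = T + T_S + T_R + T_H + V
    free = 1.0 - sigma
    # (c_min - c) * H(c_min - c); the H(0)=1 convention is immaterial because
    # the prefactor vanishes at c = c_min.
    hyp = p.c_min - c if c <= p.c_min else 0.0
    mu = p.mu0 * math.exp(-p.mu_Lambda * Lam)
    q2 = p.q2

    cR = c * R
    dT = q2 * c * free * T - (p.delta * hyp + p.lam * cR + p.nu * cR) * T \
        + mu * T_S - beta * T
    dTS = p.theta2 * q2 * c * free * T_S \
        - (p.delta_S * hyp + p.lam_S * cR + mu + p.xi) * T_S \
        + p.nu * cR * T - beta * T_S
    dTR = p.lam * cR * T + (p.lam_S * cR + p.xi) * T_S - p.eta_R * T_R
    dTH = beta * (T + T_S) - p.eta_H * T_H
    dV = p.kappa0 * T_H - beta * V
    dc = p.g * (1.0 - c) * V - (
        p.q1 * c * (T + p.theta1 * T_S)
        + p.q3 * c * free * (T + p.theta2 * T_S)
    )
    dLam = (p.k1 * (1.0 - Lam) if ht_on else 0.0) - p.k2 * Lam
    return np.array([dT, dTS, dTR, dTH, dV, dc, dLam])


def rhs(t: float, y, params: ModelParams, schedule) -> np.ndarray:
    """Full right-hand side with schedule lookup (side-effect free)."""
    beta = ht_damage_rate(t, schedule)
    return rhs_autonomous(
        y, params, rt_dose_rate(t, schedule), beta, beta > 0.0
    )
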