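"""Core phase-type stroke recovery model.

Patients traverse up to four transient recovery phases of decreasing
severity before absorption into one of three discharge modes: death,
nursing home, or the patient's usual residence.  The entry phase is set
by the stroke type — haemorrhagic strokes enter phase 1, cerebral
infarctions phase 2, and TIAs (transient ischemic attacks) split between
a severe group entering phase 3 and a mild group entering phase 4.

Phase-progression intensities are age-linked through a log link,
``lambda_i(x) = exp(gamma_i + beta_i * x)`` for phases i = 1, 2, and the
mild-TIA probability through a complementary log-log link,
``p(x) = exp(-exp(theta0 + theta1 * x))``.  Exit rates to death (mu_i),
nursing home (nu_i) and usual residence (rho_i) are age-independent.
Phase 4 can only discharge home (mu4 = nu4 = 0, structural).  All rates
are per year; lengths of stay are reported in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

#: Day-count convention used to convert per-year rates to day-scale
#: lengths of stay.
DAYS_PER_YEAR = 365.25


class StrokeType(str, Enum):
    """The three stroke diagnoses the model distinguishes."""

    HAEMORRHAGIC = "haemorrhagic"
    CEREBRAL_INFARCTION = "cerebral_infarction"
    TIA = "tia"

    @classmethod
    def parse(cls, label) -> "StrokeType":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown stroke type {label!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


class DischargeMode(str, Enum):
    """Absorbing discharge destinations, in fixed column order."""

    DEATH = "death"
    NURSING_HOME = "nursing_home"
    USUAL_RESIDENCE = "usual_residence"

    @classmethod
    def parse(cls, label) -> "DischargeMode":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown discharge mode {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: Column order of every 4x3 absorption-rate / absorption-probability matrix.
MODE_ORDER = (
    DischargeMode.DEATH,
    DischargeMode.NURSING_HOME,
    DischargeMode.USUAL_RESIDENCE,
)

#: Structural zeros: phase 4 holds only mild TIAs, who are discharged home.
STRUCTURAL_ZEROS = frozenset({"mu4", "nu4"})

#: Additional rates fixed at zero in the revised (pruned) model.
REVISED_ZEROS = frozenset({"nu1", "nu2", "rho1"})

#: Canonical parameter ordering (estimate tables, serialization).
PARAM_ORDER = (
    "gamma1", "beta1", "gamma2", "beta2", "theta0", "theta1",
    "mu1", "mu2", "mu3", "mu4",
    "nu1", "nu2", "nu3", "nu4",
    "rho1", "rho2", "rho3", "rho4",
)

RATE_NAMES = frozenset(n for n in PARAM_ORDER if n[0] in "mnr")

LINK_NAMES = ("gamma1", "beta1", "gamma2", "beta2", "theta0", "theta1")


@dataclass(frozen=True)
class ModelParams:
    """The 16-parameter vector with a structural-zero mask.

    ``zero_mask`` lists rate parameters pinned at exactly zero;
    ``mu4`` and ``nu4`` are always masked.  The default mask is the
    revised model's, which additionally zeroes ``nu1``, ``nu2`` and
    ``rho1``.
    """

    gamma1: float
    beta1: float
    gamma2: float
    beta2: float
    theta0: float
    theta1: float
    mu1: float = 0.0
    mu2: float = 0.0
    mu3: float = 0.0
    mu4: float = 0.0
    nu1: float = 0.0
    nu2: float = 0.0
    nu3: float = 0.0
    nu4: float = 0.0
    rho1: float = 0.0
    rho2: float = 0.0
    rho3: float = 0.0
    rho4: float = 0.0
    zero_mask: frozenset = field(default_factory=lambda: REVISED_ZEROS)

    def __post_init__(self) -> None:
        mask = frozenset(self.zero_mask) | STRUCTURAL_ZEROS
        unknown = mask - RATE_NAMES
        if unknown:
            raise ValueError(f"zero_mask names are not rates: {sorted(unknown)}")
        object.__setattr__(self, "zero_mask", mask)
        for name in RATE_NAMES:
            if getattr(self, name) < 0 and name not in mask:
                raise ValueError(f"rate parameter {name} must be >= 0")

    def value(self, name: str) -> float:
        """Effective value: exactly 0 for masked rates, else the stored one."""
        if name in self.zero_mask:
            return 0.0
        return float(getattr(self, name))

    def free_names(self) -> tuple:
        """Unmasked parameters, in canonical order (13 in the revised model)."""
        return tuple(n for n in PARAM_ORDER if n not in self.zero_mask)

    def with_values(self, **updates) -> "ModelParams":
        return replace(self, **updates)

    def with_mask(self, zero_mask) -> "ModelParams":
        return replace(self, zero_mask=frozenset(zero_mask))

    def as_dict(self, effective: bool = True) -> dict:
        get = self.value if effective else lambda n: float(getattr(self, n))
        return {n: get(n) for n in PARAM_ORDER}


@dataclass(frozen=True)
class GeneratorView:
    """Age- and type-specific generator blocks of the phase process.

    ``T`` (4x4) holds transition rates among transient phases, ``tA``
    (4x3) absorption rates into (death, nursing home, usual residence),
    ``alpha`` the initial-phase distribution and ``Lambda`` the total
    exit rate of each phase.  All rates are per year.
    """

    T: np.ndarray
    tA: np.ndarray
    alpha: np.ndarray
    age: float
    Lambda: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        object.__setattr__(self, "tA", np.asarray(self.tA, dtype=float))
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "Lambda", np.asarray(self.Lambda, dtype=float))


def progression_rate(phase: int, age: float, params: ModelParams) -> float:
    """Phase-progression intensity lambda_phase(age) = exp(gamma + beta*age)."""
    if phase == 1:
        gamma, beta = params.gamma1, params.beta1
    elif phase == 2:
        gamma, beta = params.gamma2, params.beta2
    else:
        raise ValueError(f"progression is defined for phases 1 and 2, got {phase}")
    if not math.isfinite(age):
        raise ValueError("age must be finite")
    return math.exp(gamma + beta * age)


def mild_tia_probability(age, params: ModelParams):
    """Probability p(age) that a TIA admission is mild (enters phase 4).

    Complementary log-log link: p = exp(-exp(theta0 + theta1*age)).
    Accepts scalars or arrays.
    """
    eta = params.theta0 + params.theta1 * np.asarray(age, dtype=float)
    p = np.exp(-np.exp(np.minimum(eta, 700.0)))
    if np.ndim(age) == 0:
        return float(p)
    return p


def build_generator(
    stroke_type: StrokeType, age: float, params: ModelParams
) -> GeneratorView:
    """Assemble the age-specific (T, tA, alpha) triple for one admission."""
    stroke_type = StrokeType.parse(stroke_type)
    if not math.isfinite(age):
        raise ValueError("age must be finite")
    lam1 = progression_rate(1, age, params)
    lam2 = progression_rate(2, age, params)
    v = params.value
    tA = np.array([
        [v("mu1"), v("nu1"), v("rho1")],
        [v("mu2"), v("nu2"), v("rho2")],
        [v("mu3"), v("nu3"), v("rho3")],
        [v("mu4"), v("nu4"), v("rho4")],
    ])
    Lambda = tA.sum(axis=1) + np.array([lam1, lam2, 0.0, 0.0])
    T = np.diag(-Lambda)
    T[0, 1] = lam1
    T[1, 2] = lam2

    if stroke_type is StrokeType.HAEMORRHAGIC:
        alpha = np.array([1.0, 0.0, 0.0, 0.0])
    elif stroke_type is StrokeType.CEREBRAL_INFARCTION:
        alpha = np.array([0.0, 1.0, 0.0, 0.0])
    else:
        p = mild_tia_probability(age, params)
        alpha = np.array([0.0, 0.0, 1.0 - p, p])
    return GeneratorView(T=T, tA=tA, alpha=alpha, age=float(age), Lambda=Lambda)
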