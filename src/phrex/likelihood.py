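"""Closed-form per-patient likelihood for the phase-type recovery model.

Because the phase process is acyclic and the admission phase is known
from the diagnosis, each patient's likelihood contribution — the joint
density of the observed length of stay and discharge mode — is a short
sum of exponential convolution kernels rather than a matrix exponential:

* TIA: a two-component mixture over the severe (phase 3) and mild
  (phase 4) entry routes;
* cerebral infarction: discharge from phase 2 directly, or after
  progressing to phase 3;
* haemorrhagic: discharge from phase 1, 2 or 3.

Contributions are evaluated as log-sum-exp of per-term logs, so large
rate-times-stay products (e.g. the phase-1 mortality rate of ~22/yr with
a long stay) cannot underflow intermediate terms.  Stays are stored in
days and converted to years exactly once, on ingestion into
:class:`CohortData`.

``oracle_density`` recomputes a contribution through a general matrix
exponential; it exists for verification and is never used in fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from ._kernels import log_k2, log_k3
from .model import (
    DAYS_PER_YEAR,
    MODE_ORDER,
    DischargeMode,
    ModelParams,
    StrokeType,
    build_generator,
)


@dataclass(frozen=True)
class PatientRecord:
    """One discharge record: diagnosis, age at admission, LOS, outcome."""

    stroke_type: StrokeType
    age: float
    los_days: float
    mode: DischargeMode

    def __post_init__(self) -> None:
        object.__setattr__(self, "stroke_type", StrokeType.parse(self.stroke_type))
        object.__setattr__(self, "mode", DischargeMode.parse(self.mode))
        if not (0.0 <= self.age <= 120.0):
            raise ValueError(f"age {self.age} outside [0, 120]")
        if not self.los_days > 0:
            raise ValueError(f"length of stay must be > 0, got {self.los_days}")


def records_to_frame(records) -> pd.DataFrame:
    """Normalise a list of records or a DataFrame to the cohort frame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "type": [StrokeType.parse(r.stroke_type).value for r in records],
                "age": [r.age for r in records],
                "los_days": [r.los_days for r in records],
                "mode": [DischargeMode.parse(r.mode).value for r in records],
            }
        )
    return df


@dataclass(frozen=True)
class CohortData:
    """Cohort pre-grouped by stroke type into flat arrays for fast evaluation."""

    groups: dict  # StrokeType -> (age, s_years, mode_idx)
    n: int

    @classmethod
    def from_records(cls, records, days_per_year: float = DAYS_PER_YEAR):
        df = records_to_frame(records)
        if len(df) == 0:
            raise ValueError("empty cohort: no patient records")
        mode_idx = df["mode"].map(
            {m.value: i for i, m in enumerate(MODE_ORDER)}
        ).to_numpy()
        groups = {}
        types = df["type"].map(lambda t: StrokeType.parse(t))
        for st in StrokeType:
            sel = (types == st).to_numpy()
            if sel.any():
                groups[st] = (
                    df.loc[sel, "age"].to_numpy(float),
                    df.loc[sel, "los_days"].to_numpy(float) / days_per_year,
                    mode_idx[sel],
                )
        return cls(groups=groups, n=len(df))


def _exit_log(rates3: np.ndarray, mode_idx: np.ndarray) -> np.ndarray:
    """log of the mode-specific exit rate; -inf where the rate is zero."""
    with np.errstate(divide="ignore"):
        return np.log(rates3)[mode_idx]


def _log_contrib_tia(age, s, mode_idx, params: ModelParams) -> np.ndarray:
    v = params.value
    r3 = v("mu3") + v("nu3") + v("rho3")
    eta = np.minimum(params.theta0 + params.theta1 * age, 700.0)
    log_p = -np.exp(eta)                      # log p(x)
    with np.errstate(divide="ignore"):
        log_1mp = np.log(-np.expm1(-np.exp(eta)))  # log(1 - p(x))
    exit3 = _exit_log(np.array([v("mu3"), v("nu3"), v("rho3")]), mode_idx)
    # phase-4 exits exist only to usual residence (mu4 = nu4 = 0, 0^0 = 1)
    exit4 = _exit_log(np.array([0.0, 0.0, v("rho4")]), mode_idx)
    t_severe = log_1mp - r3 * s + exit3
    t_mild = log_p - v("rho4") * s + exit4
    return np.logaddexp(t_severe, t_mild)


def _log_contrib_ci(age, s, mode_idx, params: ModelParams) -> np.ndarray:
    v = params.value
    log_lam2 = np.minimum(params.gamma2 + params.beta2 * age, 300.0)
    lam2 = np.exp(log_lam2)
    r2 = v("mu2") + v("nu2") + v("rho2") + lam2
    r3 = v("mu3") + v("nu3") + v("rho3")
    exit2 = _exit_log(np.array([v("mu2"), v("nu2"), v("rho2")]), mode_idx)
    exit3 = _exit_log(np.array([v("mu3"), v("nu3"), v("rho3")]), mode_idx)
    t_phase2 = -r2 * s + exit2
    t_phase3 = log_lam2 + log_k2(s, r3, r2) + exit3
    return np.logaddexp(t_phase2, t_phase3)


def _log_contrib_haem(age, s, mode_idx, params: ModelParams) -> np.ndarray:
    v = params.value
    log_lam1 = np.minimum(params.gamma1 + params.beta1 * age, 300.0)
    log_lam2 = np.minimum(params.gamma2 + params.beta2 * age, 300.0)
    lam1, lam2 = np.exp(log_lam1), np.exp(log_lam2)
    r1 = v("mu1") + v("nu1") + v("rho1") + lam1
    r2 = v("mu2") + v("nu2") + v("rho2") + lam2
    r3 = v("mu3") + v("nu3") + v("rho3")
    exit1 = _exit_log(np.array([v("mu1"), v("nu1"), v("rho1")]), mode_idx)
    exit2 = _exit_log(np.array([v("mu2"), v("nu2"), v("rho2")]), mode_idx)
    exit3 = _exit_log(np.array([v("mu3"), v("nu3"), v("rho3")]), mode_idx)
    t1 = -r1 * s + exit1
    t2 = log_lam1 + log_k2(s, r2, r1) + exit2
    t3 = log_lam1 + log_lam2 + log_k3(s, r1, r2, r3) + exit3
    return np.logaddexp(np.logaddexp(t1, t2), t3)


_LOG_CONTRIB = {
    StrokeType.TIA: _log_contrib_tia,
    StrokeType.CEREBRAL_INFARCTION: _log_contrib_ci,
    StrokeType.HAEMORRHAGIC: _log_contrib_haem,
}


def log_contributions(data: CohortData, params: ModelParams) -> np.ndarray:
    """Per-record log likelihood contributions (density per year of stay)."""
    parts = [
        _LOG_CONTRIB[st](age, s, mode_idx, params)
        for st, (age, s, mode_idx) in data.groups.items()
    ]
    return np.concatenate(parts)


def log_likelihood(records, params: ModelParams,
                   days_per_year: float = DAYS_PER_YEAR) -> float:
    """Dataset log-likelihood; -inf if any contribution underflows to zero."""
    data = records if isinstance(records, CohortData) else CohortData.from_records(
        records, days_per_year)
    logs = log_contributions(data, params)
    if not np.all(np.isfinite(logs)):
        return float("-inf")
    return float(logs.sum())


def _single(rec: PatientRecord, params: ModelParams, expected: StrokeType,
            days_per_year: float) -> float:
    if rec.stroke_type is not expected:
        raise ValueError(
            f"record has stroke type {rec.stroke_type.value}, "
            f"expected {expected.value}"
        )
    mode_idx = np.array([MODE_ORDER.index(rec.mode)])
    log_l = _LOG_CONTRIB[expected](
        np.array([rec.age]), np.array([rec.los_days / days_per_year]),
        mode_idx, params,
    )
    return float(np.exp(log_l[0]))


def contribution_tia(rec: PatientRecord, params: ModelParams,
                     days_per_year: float = DAYS_PER_YEAR) -> float:
    """Mixture likelihood contribution of a TIA record."""
    return _single(rec, params, StrokeType.TIA, days_per_year)


def contribution_ci(rec: PatientRecord, params: ModelParams,
                    days_per_year: float = DAYS_PER_YEAR) -> float:
    """Two-term likelihood contribution of a cerebral infarction record."""
    return _single(rec, params, StrokeType.CEREBRAL_INFARCTION, days_per_year)


def contribution_haem(rec: PatientRecord, params: ModelParams,
                      days_per_year: float = DAYS_PER_YEAR) -> float:
    """Three-term likelihood contribution of a haemorrhagic record."""
    return _single(rec, params, StrokeType.HAEMORRHAGIC, days_per_year)


def contribution(rec: PatientRecord, params: ModelParams,
                 days_per_year: float = DAYS_PER_YEAR) -> float:
    """Dispatch on stroke type."""
    return _single(rec, params, rec.stroke_type, days_per_year)


def oracle_density(rec: PatientRecord, params: ModelParams,
                   days_per_year: float = DAYS_PER_YEAR) -> float:
    """Mode-specific density alpha' exp(Ts) tA e_mode via a general expm.

    Verification oracle only: computes the same joint density as the
    closed-form contributions through scipy's matrix exponential.
    """
    gen = build_generator(rec.stroke_type, rec.age, params)
    s = rec.los_days / days_per_year
    E = scipy.linalg.expm(gen.T * s)
    e_mode = np.zeros(3)
    e_mode[MODE_ORDER.index(rec.mode)] = 1.0
    return float(gen.alpha @ E @ gen.tA @ e_mode)
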