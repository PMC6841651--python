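"""Seeded synthetic-cohort generator.

Samples patient discharge records by forward simulation of the phase
process: in each transient phase the sojourn is exponential with the
phase's total exit rate and the exit cause is categorical over the
competing rates (progression, death, nursing home, usual residence).
The default configuration emulates the profile of the hospital cohort
the model was developed on — 1,234 patients with a stroke-type mix of
roughly 11% haemorrhagic, 56% cerebral infarction, 33% TIA — with a
truncated-normal age distribution (mean 75, sd 10, support [40, 100])
standing in for the unpublished age profile.

The original hospital records are not public; simulated cohorts are the
package's test bed for estimation and diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .model import (
    DAYS_PER_YEAR,
    MODE_ORDER,
    DischargeMode,
    ModelParams,
    StrokeType,
    mild_tia_probability,
)

#: Stroke-type mix of the emulated cohort (haemorrhagic, infarction, TIA),
#: proportional to the published discharge counts by type.
DEFAULT_TYPE_MIX = (139 / 1256, 707 / 1256, 410 / 1256)

DEFAULT_AGE_MODEL = {"name": "truncnorm", "mean": 75.0, "sd": 10.0,
                     "low": 40.0, "high": 100.0}


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    params: ModelParams
    n: int = 1234
    type_mix: tuple = DEFAULT_TYPE_MIX
    age_model: dict = field(default_factory=lambda: dict(DEFAULT_AGE_MODEL))
    seed: int = 0
    days_per_year: float = DAYS_PER_YEAR
    round_days: bool = False  # mimic whole-day administrative granularity

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")

    def digest(self) -> str:
        payload = {
            "n": self.n,
            "type_mix": list(self.type_mix),
            "age_model": self.age_model,
            "seed": self.seed,
            "days_per_year": self.days_per_year,
            "round_days": self.round_days,
            "params": self.params.as_dict(effective=False),
            "zero_mask": sorted(self.params.zero_mask),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def sample_ages(age_model: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if age_model.get("name", "truncnorm") != "truncnorm":
        raise ValueError(f"unknown age model {age_model.get('name')!r}")
    mean, sd = age_model["mean"], age_model["sd"]
    low, high = age_model["low"], age_model["high"]
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _simulate_paths(
    start_phase: np.ndarray,
    ages: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple:
    """Competing-exponentials path simulation; returns (los_years, mode_idx)."""
    n = len(ages)
    v = params.value
    lam = np.zeros((n, 4))
    lam[:, 0] = np.exp(params.gamma1 + params.beta1 * ages)
    lam[:, 1] = np.exp(params.gamma2 + params.beta2 * ages)
    exits = np.array([
        [v("mu1"), v("nu1"), v("rho1")],
        [v("mu2"), v("nu2"), v("rho2")],
        [v("mu3"), v("nu3"), v("rho3")],
        [v("mu4"), v("nu4"), v("rho4")],
    ])

    los = np.zeros(n)
    mode_idx = np.full(n, -1)
    phase = start_phase.copy()
    for i in range(4):
        active = (mode_idx < 0) & (phase == i)
        if not active.any():
            continue
        m = int(active.sum())
        rates = np.empty((m, 4))  # progress, death, nursing home, home
        rates[:, 0] = lam[active, i]
        rates[:, 1:] = exits[i]
        total = rates.sum(axis=1)
        los[active] += rng.exponential(1.0 / total)
        cause = (rng.random(m)[:, None] > np.cumsum(rates, axis=1) / total[:, None]
                 ).sum(axis=1)
        progressed = cause == 0
        idx = np.flatnonzero(active)
        phase[idx[progressed]] = i + 1
        done = idx[~progressed]
        mode_idx[done] = cause[~progressed] - 1
    assert (mode_idx >= 0).all(), "all paths must absorb"
    return los, mode_idx


def simulate_patient(
    stroke_type: StrokeType,
    age: float,
    params: ModelParams,
    rng: np.random.Generator,
    days_per_year: float = DAYS_PER_YEAR,
):
    """Draw a single patient record at a fixed type and age."""
    from .likelihood import PatientRecord

    stroke_type = StrokeType.parse(stroke_type)
    start = _start_phases(np.array([_TYPE_IDX[stroke_type]]),
                          np.array([age]), params, rng)
    los, mode_idx = _simulate_paths(start, np.array([float(age)]), params, rng)
    return PatientRecord(
        stroke_type=stroke_type,
        age=float(age),
        los_days=float(los[0] * days_per_year),
        mode=MODE_ORDER[int(mode_idx[0])],
    )


_TYPE_IDX = {StrokeType.HAEMORRHAGIC: 0, StrokeType.CEREBRAL_INFARCTION: 1,
             StrokeType.TIA: 2}
_TYPES = tuple(_TYPE_IDX)


def _start_phases(type_idx, ages, params, rng) -> np.ndarray:
    """Entry phase (0-based): haem -> 0, CI -> 1, TIA -> 2 or 3 (mild)."""
    start = type_idx + 0  # haem 0, ci 1, tia 2
    start = np.where(type_idx == 2, 2, type_idx)
    tia = type_idx == 2
    if tia.any():
        p_mild = mild_tia_probability(ages[tia], params)
        start[tia] = np.where(rng.random(int(tia.sum())) < p_mild, 3, 2)
    return start


def simulate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Draw a full cohort; reproducible for a fixed config (incl. seed).

    Returns the cohort frame (columns ``type, age, los_days, mode``) with
    provenance recorded in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(cfg.seed)
    type_idx = rng.choice(3, size=cfg.n, p=np.asarray(cfg.type_mix, float))
    ages = sample_ages(cfg.age_model, cfg.n, rng)
    start = _start_phases(type_idx, ages, cfg.params, rng)
    los_years, mode_idx = _simulate_paths(start, ages, cfg.params, rng)
    los_days = los_years * cfg.days_per_year
    if cfg.round_days:
        los_days = np.maximum(np.round(los_days), 1.0)
    df = pd.DataFrame(
        {
            "type": [_TYPES[i].value for i in type_idx],
            "age": ages,
            "los_days": los_days,
            "mode": [MODE_ORDER[i].value for i in mode_idx],
        }
    )
    df.attrs["provenance"] = {
        "generator": "phrex.simulate.simulate_cohort",
        "seed": cfg.seed,
        "n": cfg.n,
        "config_sha": cfg.digest(),
    }
    return df


def summarize_cohort(records) -> pd.DataFrame:
    """Discharge counts and mean LOS (days) by stroke type and mode.

    Same layout as the standard cohort summary table: one block of
    counts and one of average stays, modes as rows, stroke types as
    columns.  Empty cells have count 0 and no mean.
    """
    from .likelihood import records_to_frame

    df = records_to_frame(records)
    types = [t.value for t in _TYPES]
    modes = [m.value for m in MODE_ORDER]
    counts = (
        df.groupby(["mode", "type"], observed=False).size()
        .unstack("type").reindex(index=modes, columns=types).fillna(0).astype(int)
    )
    means = (
        df.groupby(["mode", "type"], observed=False)["los_days"].mean()
        .unstack("type").reindex(index=modes, columns=types)
    )
    out = pd.concat({"count": counts, "mean_los_days": means},
                    names=["statistic", "mode"])
    return out
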