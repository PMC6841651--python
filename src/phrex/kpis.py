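"""Key performance indicators of the phase-type recovery model.

Length-of-stay (LOS) density / distribution, absorption (discharge
destination) probabilities, overall and destination-conditional mean
LOS, mean residual stay, destination probabilities conditional on the
stay incurred so far, and the standard report tables by age and stroke
type.

All public functions take stays in days; internally the generator works
in per-year rates and times are converted once at the boundary using
``days_per_year`` (default 365.25).

Because the transient generator ``T`` is upper-bidiagonal, exp(Ty) has a
closed form in the exponential divided-difference kernels of
:mod:`phrex._kernels`; no general matrix exponential is needed, and
near-equal total exit rates are handled by the kernels' confluent limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from ._kernels import k2, k3
from .model import (
    DAYS_PER_YEAR,
    MODE_ORDER,
    DischargeMode,
    GeneratorView,
    ModelParams,
    StrokeType,
    build_generator,
)


@dataclass(frozen=True)
class AbsorptionMatrix:
    """P = (-T)^{-1} tA: phase-by-destination absorption probabilities."""

    P: np.ndarray  # 4x3, rows = starting phase, cols = MODE_ORDER

    def row(self, phase: int) -> np.ndarray:
        """1-based phase row."""
        return self.P[phase - 1]


def _check_y(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("length of stay must be non-negative")
    return y


def transient_matrix_exp(gen: GeneratorView, y_years) -> np.ndarray:
    """exp(T y) for the upper-bidiagonal transient generator, closed form.

    ``y_years`` may be a scalar or array; the result has shape
    ``y.shape + (4, 4)``.
    """
    y = np.asarray(y_years, dtype=float)
    L = gen.Lambda
    lam1, lam2 = gen.T[0, 1], gen.T[1, 2]
    out = np.zeros(y.shape + (4, 4))
    for i in range(4):
        out[..., i, i] = np.exp(-L[i] * y)
    out[..., 0, 1] = lam1 * k2(y, L[0], L[1])
    out[..., 1, 2] = lam2 * k2(y, L[1], L[2])
    out[..., 0, 2] = lam1 * lam2 * k3(y, L[0], L[1], L[2])
    return out


def phase_occupancy(gen: GeneratorView, y_years) -> np.ndarray:
    """alpha' exp(Ty): probability of being in each phase at time y (years)."""
    E = transient_matrix_exp(gen, y_years)
    return np.einsum("i,...ij->...j", gen.alpha, E)


def _neg_T_inv_apply(gen: GeneratorView, b: np.ndarray) -> np.ndarray:
    """Solve (-T) x = b by back-substitution on the triangular block."""
    return solve_triangular(-gen.T, b, lower=False)


def survival(y_days, gen: GeneratorView, days_per_year: float = DAYS_PER_YEAR):
    """P(X > y) = alpha' exp(Ty) 1."""
    y = _check_y(y_days) / days_per_year
    return phase_occupancy(gen, y).sum(axis=-1)


def los_cdf(y_days, gen: GeneratorView, days_per_year: float = DAYS_PER_YEAR):
    """F_X(y) = 1 - alpha' exp(Ty) 1."""
    return 1.0 - survival(y_days, gen, days_per_year)


def los_density(y_days, gen: GeneratorView, days_per_year: float = DAYS_PER_YEAR):
    """LOS density per day, f_X(y) = alpha' exp(Ty) tA 1 / days_per_year."""
    y = _check_y(y_days) / days_per_year
    occ = phase_occupancy(gen, y)
    return occ @ gen.tA.sum(axis=1) / days_per_year


def absorption_probs(gen: GeneratorView) -> AbsorptionMatrix:
    """P = (-T)^{-1} tA, the phase-by-destination absorption matrix."""
    if np.any(gen.Lambda <= 0):
        raise ValueError("degenerate model: some phase has no exit rate")
    return AbsorptionMatrix(P=_neg_T_inv_apply(gen, gen.tA))


def mean_los(gen: GeneratorView, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Overall mean LOS in days, E{X} = alpha' (-T)^{-1} 1."""
    return float(gen.alpha @ _neg_T_inv_apply(gen, np.ones(4))) * days_per_year


def mean_los_by_destination(
    gen: GeneratorView,
    mode: DischargeMode,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """E{X | discharge mode} = alpha'(-T)^{-1} P_m / (alpha' P_m), in days."""
    mode = DischargeMode.parse(mode)
    Pm = absorption_probs(gen).P[:, MODE_ORDER.index(mode)]
    reach = float(gen.alpha @ Pm)
    if reach <= 0:
        raise ValueError(f"mode {mode.value} is unreachable; conditional mean undefined")
    return float(gen.alpha @ _neg_T_inv_apply(gen, Pm)) / reach * days_per_year


def mean_residual(
    y_days, gen: GeneratorView, days_per_year: float = DAYS_PER_YEAR
):
    """Mean residual stay E{X - y | X > y} in days.

    As y grows this converges to the phase-3 exponential mean
    days_per_year / (mu3 + nu3 + rho3) for every stroke type, since
    phase 3 is the last common recovery stage.
    """
    y = _check_y(y_days) / days_per_year
    occ = phase_occupancy(gen, y)
    surv = occ.sum(axis=-1)
    if np.any(surv <= 0):
        raise ValueError("survival underflows to 0 at the requested stay")
    m = _neg_T_inv_apply(gen, np.ones(4))
    return (occ @ m) / surv * days_per_year


def destination_probs_given_stay(
    y_days, gen: GeneratorView, days_per_year: float = DAYS_PER_YEAR
):
    """P(mode | X > y): destination probabilities given stay incurred so far."""
    y = _check_y(y_days) / days_per_year
    occ = phase_occupancy(gen, y)
    surv = occ.sum(axis=-1)
    if np.any(surv <= 0):
        raise ValueError("survival underflows to 0 at the requested stay")
    P = absorption_probs(gen).P
    return (occ @ P) / surv[..., None]


def cumulative_discharge_by_mode(
    y_days,
    gen: GeneratorView,
    mode: DischargeMode,
    days_per_year: float = DAYS_PER_YEAR,
):
    """P(X <= y, discharge mode = m) = alpha'(I - exp(Ty)) P e_m.

    The mode-specific sub-distribution function; summed over the three
    modes it equals the LOS distribution function.
    """
    mode = DischargeMode.parse(mode)
    y = _check_y(y_days) / days_per_year
    occ = phase_occupancy(gen, y)
    Pm = absorption_probs(gen).P[:, MODE_ORDER.index(mode)]
    return float(gen.alpha @ Pm) - occ @ Pm


def destination_percentages(
    age: float, stroke_type: StrokeType, params: ModelParams
) -> np.ndarray:
    """alpha'P as percentages (death, nursing home, usual residence), unrounded."""
    gen = build_generator(stroke_type, age, params)
    return gen.alpha @ absorption_probs(gen).P * 100.0


def round_half_up(x, decimals: int = 1):
    """Round with ties away from zero, as in the printed report tables."""
    factor = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


_TYPE_LABELS = {
    StrokeType.HAEMORRHAGIC: "Haemorrhagic",
    StrokeType.CEREBRAL_INFARCTION: "Cerebral infarction",
    StrokeType.TIA: "TIA",
}
_MODE_COLUMNS = ("death", "nursing_home", "usual_residence")


def make_table3(
    ages, params: ModelParams, rounded: bool = True
) -> pd.DataFrame:
    """Ultimate destination percentages by age and stroke type."""
    rows = []
    index = []
    for age in ages:
        for st in StrokeType:
            rows.append(destination_percentages(age, st, params))
            index.append((age, _TYPE_LABELS[st]))
    out = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["age", "stroke_type"]),
        columns=list(_MODE_COLUMNS),
    )
    return out.apply(round_half_up) if rounded else out


def make_table4(
    ages,
    params: ModelParams,
    rounded: bool = True,
    days_per_year: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Mean LOS in days by age, stroke type and ultimate destination."""
    rows = []
    index = []
    for age in ages:
        for st in StrokeType:
            gen = build_generator(st, age, params)
            row = [
                mean_los_by_destination(gen, m, days_per_year) for m in MODE_ORDER
            ]
            row.append(mean_los(gen, days_per_year))
            rows.append(row)
            index.append((age, _TYPE_LABELS[st]))
    out = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["age", "stroke_type"]),
        columns=list(_MODE_COLUMNS) + ["all"],
    )
    return out.apply(round_half_up) if rounded else out
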