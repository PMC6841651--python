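"""Staged backward maximum-likelihood estimation.

Because the diagnosis identifies the admission phase, the data can be
fitted backwards through the severity scale: TIA records inform the
phase-3/4 parameters, infarction records add phase 2, haemorrhagic
records add phase 1, and a final joint fit over all records polishes
everything.  The five stages are:

1. TIA only            -> theta0, theta1, mu3, nu3, rho3, rho4
2. infarction only     -> gamma2, beta2, mu2, nu2, rho2   (stage 1 fixed)
3. TIA + infarction    -> joint update of all 11
4. haemorrhagic only   -> gamma1, beta1, mu1, nu1, rho1   (others fixed)
5. all data            -> all unmasked parameters jointly

Rates are optimized on the log scale (positivity); the link coefficients
gamma, beta, theta are unconstrained.  The objective is the negative
mean log-likelihood (per observation), which keeps finite-difference
gradients well scaled regardless of cohort size.  Standard errors come
from the observed information (negative Hessian of the log-likelihood at
the MLE, central finite differences on the transformed scale), mapped to
the natural scale by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import CohortData, log_contributions, records_to_frame
from .model import (
    DAYS_PER_YEAR,
    PARAM_ORDER,
    RATE_NAMES,
    REVISED_ZEROS,
    STRUCTURAL_ZEROS,
    ModelParams,
    StrokeType,
)

#: The optimizer works on an age-centered parameterization: each link
#: intercept is replaced by the linear predictor at AGE_CENTER years
#: (gamma + AGE_CENTER * beta).  Raw age multiplies the slope by ~75,
#: which makes the slope direction far steeper than the intercept's and
#: drives quasi-Newton line searches onto the degenerate lambda -> inf
#: plateau; centering equalizes the scales.  Reported estimates are
#: always on the natural (uncentered) scale.
AGE_CENTER = 70.0

_PAIRS = {"gamma1": "beta1", "gamma2": "beta2", "theta0": "theta1"}
_SLOPE_NAMES = frozenset(_PAIRS.values())

#: Transformed-scale bounds: log-rates, centered link intercepts (the log
#: rate / cloglog predictor at AGE_CENTER), and per-year age slopes.
_LOG_RATE_BOUNDS = (-20.0, 9.0)
_INTERCEPT_BOUNDS = (-30.0, 12.0)
_SLOPE_BOUNDS = (-1.0, 1.0)

_STAGE1 = ("theta0", "theta1", "mu3", "nu3", "rho3", "rho4")
_STAGE2 = ("gamma2", "beta2", "mu2", "nu2", "rho2")
_STAGE4 = ("gamma1", "beta1", "mu1", "nu1", "rho1")

_STAGES = (
    ("tia", (StrokeType.TIA,), _STAGE1),
    ("infarction", (StrokeType.CEREBRAL_INFARCTION,), _STAGE2),
    ("tia+infarction",
     (StrokeType.TIA, StrokeType.CEREBRAL_INFARCTION), _STAGE1 + _STAGE2),
    ("haemorrhagic", (StrokeType.HAEMORRHAGIC,), _STAGE4),
    ("all", tuple(StrokeType), _STAGE1 + _STAGE2 + _STAGE4),
)


class ConvergenceError(RuntimeError):
    """Raised when a fitting stage fails to converge; carries the trace."""

    def __init__(self, message, stage_trace):
        super().__init__(message)
        self.stage_trace = stage_trace


@dataclass
class StageResult:
    name: str
    free_names: tuple
    loglik: float
    converged: bool
    nfev: int


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, uncertainty, and stage trace."""

    params: ModelParams
    free_names: tuple
    cov: np.ndarray          # natural-scale asymptotic covariance
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    stage_trace: list = field(default_factory=list)
    info_pd: bool = True
    seed: int | None = None
    n: int = 0


def _is_rate(name: str) -> bool:
    return name in RATE_NAMES


def _pack(params: ModelParams, free) -> np.ndarray:
    x = []
    for name in free:
        val = float(getattr(params, name))
        if _is_rate(name):
            x.append(np.log(max(val, 1e-9)))
        elif name in _PAIRS:  # intercept -> predictor at AGE_CENTER
            x.append(val + AGE_CENTER * float(getattr(params, _PAIRS[name])))
        else:
            x.append(val)
    return np.array(x)


def _unpack(x: np.ndarray, free, base: ModelParams) -> ModelParams:
    vals = dict(zip(free, x))
    updates = {}
    for name, xi in vals.items():
        if _is_rate(name):
            updates[name] = float(np.exp(xi))
        elif name in _PAIRS:
            slope = vals.get(_PAIRS[name], float(getattr(base, _PAIRS[name])))
            updates[name] = float(xi - AGE_CENTER * slope)
        else:
            updates[name] = float(xi)
    return base.with_values(**updates)


def _bounds(free):
    out = []
    for n in free:
        if _is_rate(n):
            out.append(_LOG_RATE_BOUNDS)
        elif n in _SLOPE_NAMES:
            out.append(_SLOPE_BOUNDS)
        else:
            out.append(_INTERCEPT_BOUNDS)
    return out


def _neg_mean_loglik(data: CohortData, base: ModelParams, free):
    def f(x):
        p = _unpack(x, free, base)
        logs = log_contributions(data, p)
        return -float(np.maximum(logs, -700.0).sum()) / data.n
    return f


def _grad_norm(f, x, h: float = 1e-6) -> float:
    g = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return float(np.linalg.norm(g))


def _optimize_stage(data, base, free, x0=None):
    f = _neg_mean_loglik(data, base, free)
    if x0 is None:
        x0 = _pack(base, free)
    res = optimize.minimize(
        f, x0, method="L-BFGS-B", bounds=_bounds(free),
        options={"maxiter": 1000, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-8},
    )
    converged = bool(res.success) or _grad_norm(f, res.x) < 1e-3
    return res, converged


def numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps h_i(1+|x_i|)."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def observed_information(
    records,
    params_at_mle: ModelParams,
    free=None,
    days_per_year: float = DAYS_PER_YEAR,
):
    """Asymptotic covariance from the observed information at the MLE.

    The information is the negative Hessian of the log-likelihood with
    respect to the transformed (log-rate) parameters; its inverse is
    mapped to the natural scale by the delta method.  Returns
    ``(cov_natural, is_positive_definite)``.
    """
    data = records if isinstance(records, CohortData) else CohortData.from_records(
        records, days_per_year)
    if free is None:
        free = params_at_mle.free_names()
    x = _pack(params_at_mle, free)

    def nll(xv):
        p = _unpack(xv, free, params_at_mle)
        return -float(np.maximum(log_contributions(data, p), -700.0).sum())

    info = numeric_hessian(nll, x)
    info = 0.5 * (info + info.T)
    eigvals = np.linalg.eigvalsh(info)
    is_pd = bool(eigvals.min() > 0)
    if is_pd:
        cov_t = np.linalg.inv(info)
    else:
        warnings.warn(
            "observed information is not positive definite; "
            "using a pseudo-inverse", RuntimeWarning)
        cov_t = np.linalg.pinv(info)
    # delta method back to the natural scale: exp for log-rates, and the
    # intercept = (centered predictor) - AGE_CENTER * slope recombination
    k = len(free)
    jac = np.zeros((k, k))
    for i, n in enumerate(free):
        if _is_rate(n):
            jac[i, i] = float(getattr(params_at_mle, n))
        else:
            jac[i, i] = 1.0
            if n in _PAIRS and _PAIRS[n] in free:
                jac[i, free.index(_PAIRS[n])] = -AGE_CENTER
    cov_nat = jac @ cov_t @ jac.T
    return cov_nat, is_pd


def _wald(params: ModelParams, free, cov: np.ndarray):
    est = np.array([float(getattr(params, n)) for n in free])
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return est, se, z, p


def fit_staged(
    records,
    init_overrides: dict | None = None,
    seed: int | None = 0,
    zero_mask=REVISED_ZEROS,
    restarts: int = 3,
    days_per_year: float = DAYS_PER_YEAR,
    strict: bool = True,
) -> FitResult:
    """Run the five-stage backward estimation and return the joint fit.

    ``zero_mask`` selects the model variant (default: the revised model
    with nu1 = nu2 = rho1 = 0; pass ``frozenset()`` for the full
    16-parameter model).  The final joint stage restarts from
    ``restarts`` jittered starting points (seeded) and keeps the best.
    """
    frame = records_to_frame(records)
    mask = frozenset(zero_mask) | STRUCTURAL_ZEROS
    base = _initial_params(frame, mask, days_per_year)
    if init_overrides:
        base = base.with_values(**{k: float(v) for k, v in init_overrides.items()})
    rng = np.random.default_rng(seed)

    present = {StrokeType.parse(t) for t in frame["type"].unique()}
    if present != set(StrokeType):
        warnings.warn(
            f"cohort lacks some stroke types ({sorted(t.value for t in present)}); "
            "running a partial pipeline", RuntimeWarning)

    trace: list[StageResult] = []
    for name, types, stage_free in _STAGES:
        stage_types = [t for t in types if t in present]
        free = tuple(n for n in stage_free if n not in mask)
        if not stage_types or not free:
            continue
        sub = frame[frame["type"].isin([t.value for t in stage_types])]
        data = CohortData.from_records(sub, days_per_year)
        if name == "all" and restarts > 1:
            best = None
            x0 = _pack(base, free)
            for r in range(restarts):
                xr = x0 if r == 0 else x0 + rng.normal(0.0, 0.05, size=len(x0))
                res, conv = _optimize_stage(data, base, free, xr)
                if best is None or res.fun < best[0].fun:
                    best = (res, conv)
            res, converged = best
        else:
            res, converged = _optimize_stage(data, base, free)
        base = _unpack(res.x, free, base)
        trace.append(StageResult(
            name=name, free_names=free, loglik=-res.fun * data.n,
            converged=converged, nfev=int(res.nfev),
        ))
        if strict and not converged:
            raise ConvergenceError(f"stage {name!r} did not converge", trace)

    full_data = CohortData.from_records(frame, days_per_year)
    free = base.free_names()
    cov, is_pd = observed_information(full_data, base, free, days_per_year)
    _, se, z, p = _wald(base, free, cov)
    loglik = float(log_contributions(full_data, base).sum())
    return FitResult(
        params=base, free_names=free, cov=cov, se=se, z=z, p=p,
        loglik=loglik, stage_trace=trace, info_pd=is_pd,
        seed=seed, n=full_data.n,
    )


def z_tests(fit: FitResult) -> pd.DataFrame:
    """Wald tests per free parameter, formatted as an estimates table."""
    return pd.DataFrame(
        {
            "estimate": [float(getattr(fit.params, n)) for n in fit.free_names],
            "std_error": fit.se,
            "z_stat": fit.z,
            "p_value": fit.p,
        },
        index=pd.Index(fit.free_names, name="parameter"),
    )


def _check_prunable(mask: frozenset) -> None:
    """Refuse masks that disconnect a phase from every absorbing mode."""
    if {"mu3", "nu3", "rho3"} <= mask:
        raise ValueError("cannot prune all phase-3 exit rates: "
                         "phases 1-3 would never absorb")
    if "rho4" in mask:
        raise ValueError("cannot prune rho4: phase 4 would never absorb")


def prune_rates(
    fit: FitResult,
    records,
    p_threshold: float = 0.90,
    rate_floor: float = 0.1,
    seed: int | None = 0,
    days_per_year: float = DAYS_PER_YEAR,
) -> FitResult:
    """Zero out statistically negligible exit rates and refit.

    A free rate parameter is pruned when its Wald p-value exceeds
    ``p_threshold`` (default 0.90) and its estimate is below
    ``rate_floor`` per year; the model is then refitted jointly with the
    enlarged zero mask, starting from the current estimates.
    """
    table = z_tests(fit)
    pruned = [
        n for n in fit.free_names
        if _is_rate(n)
        and table.loc[n, "p_value"] > p_threshold
        and abs(table.loc[n, "estimate"]) < rate_floor
    ]
    if not pruned:
        return fit
    new_mask = frozenset(fit.params.zero_mask) | frozenset(pruned)
    _check_prunable(new_mask)

    frame = records_to_frame(records)
    data = CohortData.from_records(frame, days_per_year)
    base = fit.params.with_mask(new_mask)
    free = base.free_names()
    res, converged = _optimize_stage(data, base, free)
    base = _unpack(res.x, free, base)
    trace = list(fit.stage_trace) + [StageResult(
        name=f"pruned({','.join(sorted(pruned))})", free_names=free,
        loglik=-res.fun * data.n, converged=converged, nfev=int(res.nfev),
    )]
    if not converged:
        raise ConvergenceError("refit after pruning did not converge", trace)
    cov, is_pd = observed_information(data, base, free, days_per_year)
    _, se, z, p = _wald(base, free, cov)
    return FitResult(
        params=base, free_names=free, cov=cov, se=se, z=z, p=p,
        loglik=float(log_contributions(data, base).sum()),
        stage_trace=trace, info_pd=is_pd, seed=seed, n=data.n,
    )


def _initial_params(frame: pd.DataFrame, mask: frozenset,
                    days_per_year: float) -> ModelParams:
    """Method-of-moments starting values from mode-specific mean stays."""
    agebar = float(frame["age"].mean()) if len(frame) else 75.0

    def group(st: StrokeType) -> pd.DataFrame:
        return frame[frame["type"] == st.value]

    def safe_rate(mean_days, default):
        if mean_days and np.isfinite(mean_days) and mean_days > 0:
            return float(np.clip(days_per_year / mean_days, 0.05, 400.0))
        return default

    # --- TIA: mild/severe split from short home discharges ---
    tia = group(StrokeType.TIA)
    theta0, theta1 = -8.0, 0.08
    mu3 = nu3 = 1.0
    rho3, rho4 = 3.0, 50.0
    if len(tia):
        mild = (tia["mode"] == "usual_residence") & (tia["los_days"] < 7.0)
        ph = float(np.clip(mild.mean(), 0.02, 0.98))
        theta1 = 0.05
        theta0 = float(np.log(-np.log(ph)) - theta1 * agebar)
        if mild.any():
            rho4 = safe_rate(tia.loc[mild, "los_days"].mean(), rho4)
        severe = tia[~mild]
        if len(severe):
            rtot = safe_rate(severe["los_days"].mean(), 6.0)
            counts = severe["mode"].value_counts()
            fr = (counts.reindex(
                ["death", "nursing_home", "usual_residence"]).fillna(0.0) + 0.5)
            fr = fr / fr.sum()
            mu3 = max(fr["death"] * rtot, 0.05)
            nu3 = max(fr["nursing_home"] * rtot, 0.05)
            rho3 = max(fr["usual_residence"] * rtot, 0.05)

    def entry_stage(st: StrokeType, defaults):
        """(gamma, mu, nu, rho) start for a direct-entry phase: split the
        total exit rate half to progression, half by observed modes."""
        g = group(st)
        if not len(g):
            return defaults
        rtot = safe_rate(g["los_days"].mean(), 10.0)
        counts = g["mode"].value_counts()
        fr = (counts.reindex(
            ["death", "nursing_home", "usual_residence"]).fillna(0.0) + 0.5)
        fr = fr / fr.sum()
        gamma = float(np.log(0.5 * rtot))
        return (
            gamma,
            max(0.5 * rtot * fr["death"], 0.05),
            max(0.5 * rtot * fr["nursing_home"], 0.05),
            max(0.5 * rtot * fr["usual_residence"], 0.05),
        )

    gamma2, mu2, nu2, rho2 = entry_stage(
        StrokeType.CEREBRAL_INFARCTION, (1.0, 1.0, 0.5, 5.0))
    gamma1, mu1, nu1, rho1 = entry_stage(
        StrokeType.HAEMORRHAGIC, (2.0, 5.0, 0.5, 1.0))

    return ModelParams(
        gamma1=gamma1, beta1=0.0, gamma2=gamma2, beta2=0.0,
        theta0=theta0, theta1=theta1,
        mu1=mu1, mu2=mu2, mu3=mu3,
        nu1=nu1, nu2=nu2, nu3=nu3,
        rho1=rho1, rho2=rho2, rho3=rho3, rho4=rho4,
        zero_mask=mask,
    )
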