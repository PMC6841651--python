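"""Stable exponential convolution kernels.

The sojourn-time algebra of an acyclic phase process reduces to the
symmetric, non-negative kernels

    K1(s; a)       = exp(-a s)
    K2(s; a, b)    = (exp(-a s) - exp(-b s)) / (b - a)
    K3(s; a, b, c) = (K2(s; a, c) - K2(s; b, c)) / (b - a)

which are, up to the product of the traversed transition rates, the
densities of sums of independent exponential sojourns (hypoexponential
kernels).  Equivalently they are signed divided differences of
r -> exp(-r s), so repeated rates have well-defined confluent limits
(K2 -> s e^{-as}, K3 -> s^2 e^{-as}/2).

Everything is evaluated in a shifted form that factors out exp(-min(r) s),
so the kernels stay accurate for near-equal rates and never overflow; the
remaining removable singularities are handled by switching to a local
derivative expansion when the scaled rate gap falls below ``TIE_RTOL``.
All functions broadcast over numpy arrays.
"""

from __future__ import annotations

import numpy as np

# Relative rate-gap below which the confluent (repeated-rate) expansion is
# used.  The switchover is continuous to ~1e-12 in the kernel value.
TIE_RTOL = 1e-7


def _phi(u: np.ndarray) -> np.ndarray:
    """phi(u) = (1 - exp(-u)) / u for u >= 0, with phi(0) = 1."""
    u = np.asarray(u, dtype=float)
    safe = np.where(u == 0.0, 1.0, u)
    out = -np.expm1(-safe) / safe
    return np.where(u == 0.0, 1.0, out)


def _phi_prime(u: np.ndarray) -> np.ndarray:
    """phi'(u) = (exp(-u)(1+u) - 1) / u^2, series-expanded near 0."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-4
    safe = np.where(small, 1.0, u)
    direct = (np.exp(-safe) * (1.0 + safe) - 1.0) / safe**2
    series = -0.5 + u / 3.0 - u**2 / 8.0
    return np.where(small, series, direct)


def _psi(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """psi(u, v) = (phi(u) - phi(v)) / (v - u) for 0 <= u <= v.

    Divided difference of -phi; positive because phi is decreasing.
    Confluent limit psi(u, u) = -phi'(u).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    gap = v - u
    tie = gap <= TIE_RTOL * np.maximum(1.0, v)
    safe_gap = np.where(tie, 1.0, gap)
    direct = (_phi(u) - _phi(v)) / safe_gap
    confluent = -_phi_prime(0.5 * (u + v))
    return np.where(tie, confluent, direct)


def k2(s, a, b) -> np.ndarray:
    """K2(s; a, b) = (e^{-as} - e^{-bs})/(b - a); symmetric, >= 0 for s >= 0."""
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = np.minimum(a, b)
    d = np.abs(b - a)
    return s * np.exp(-lo * s) * _phi(d * s)


def k3(s, a, b, c) -> np.ndarray:
    """K3(s; a, b, c); symmetric hypoexponential kernel for three rates."""
    s = np.asarray(s, dtype=float)
    r = np.sort(np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)),
        axis=0)
    r0, r1, r2 = r[0], r[1], r[2]
    u = (r1 - r0) * s
    v = (r2 - r0) * s
    return s**2 * np.exp(-r0 * s) * _psi(u, v)


def log_k2(s, a, b) -> np.ndarray:
    """log K2, stable for large rate*time products (K2 may underflow)."""
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = np.minimum(a, b)
    d = np.abs(b - a)
    with np.errstate(divide="ignore"):
        return np.log(s) - lo * s + np.log(_phi(d * s))


def log_k3(s, a, b, c) -> np.ndarray:
    """log K3, stable for large rate*time products."""
    s = np.asarray(s, dtype=float)
    r = np.sort(np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)),
        axis=0)
    r0, r1, r2 = r[0], r[1], r[2]
    u = (r1 - r0) * s
    v = (r2 - r0) * s
    with np.errstate(divide="ignore"):
        return 2.0 * np.log(s) - r0 * s + np.log(_psi(u, v))
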