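"""Compiled scalar kernels for the optimizer's hot path.

These mirror the vectorised reference implementations in ``models.cpmg``
point for point (including the vanishing-exchange branches and the
large-argument asymptotics) and exist purely to cut per-evaluation
overhead inside the simplex loop.  The reference implementations remain
the public surface; a test asserts the two routes agree.

If numba is unavailable the plain-Python versions are used as-is, which
is correct but slower.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["cr72_rates", "lm63_rates", "it99_rates", "tsmfk01_rates", "JITTED"]

_ETA_SCALE = 1.0 / (2.0 * math.sqrt(2.0))


def _cr72_rates(r20, pA, kex, dw, nu, out):  # pragma: no cover - jitted
    n = r20.shape[0]
    pB = 1.0 - pA
    for i in range(n):
        if pA == 1.0 or kex == 0.0 or dw[i] == 0.0:
            out[i] = r20[i]
            continue
        dw2 = dw[i] * dw[i]
        fact = -pA * kex + pB * kex  # equal baseline rates for both states
        psi = fact * fact - dw2 + 4.0 * pA * pB * kex * kex
        zeta = 2.0 * dw[i] * fact
        root = math.hypot(psi, zeta)
        d_common = (psi + 2.0 * dw2) / root
        d_pos = 0.5 * (1.0 + d_common)
        d_neg = 0.5 * (-1.0 + d_common)
        ep = psi + root
        en = root - psi
        if ep < 0.0:
            ep = 0.0
        if en < 0.0:
            en = 0.0
        eta_pos = _ETA_SCALE * math.sqrt(ep) / nu[i]
        eta_neg = _ETA_SCALE * math.sqrt(en) / nu[i]
        if eta_pos > 300.0:
            dp = d_pos if d_pos > 1e-300 else 1e-300
            acosh_term = eta_pos + math.log(dp)
        else:
            arg = d_pos * math.cosh(eta_pos) - d_neg * math.cos(eta_neg)
            if arg < 1.0:
                arg = 1.0
            acosh_term = math.acosh(arg)
        out[i] = r20[i] + 0.5 * kex - nu[i] * acosh_term


def _lm63_rates(r20, phi_ex, kex, nu, out):  # pragma: no cover - jitted
    for i in range(r20.shape[0]):
        if phi_ex[i] == 0.0:
            out[i] = r20[i]
        else:
            x = kex / (4.0 * nu[i])
            out[i] = r20[i] + (phi_ex[i] / kex) * (1.0 - math.tanh(x) / x)


def _it99_rates(r20, pA, kex, dw, nu, out):  # pragma: no cover - jitted
    pB = 1.0 - pA
    for i in range(r20.shape[0]):
        if pA == 1.0 or kex == 0.0 or dw[i] == 0.0:
            out[i] = r20[i]
            continue
        tcp = 1.0 / (2.0 * nu[i])
        denom = kex * kex + math.sqrt(pA * pA * dw[i] ** 4 + 144.0 / tcp**4)
        out[i] = r20[i] + pA * pB * dw[i] * dw[i] * kex / denom


def _tsmfk01_rates(r2a0, k_ab, dw, nu, out):  # pragma: no cover - jitted
    for i in range(r2a0.shape[0]):
        if k_ab == 0.0 or dw[i] == 0.0:
            out[i] = r2a0[i]
            continue
        x = dw[i] / (2.0 * nu[i])
        sinc = math.sin(x) / x if abs(x) > 1e-8 else 1.0 - x * x / 6.0
        out[i] = r2a0[i] + k_ab - k_ab * sinc


try:  # compile when numba is present
    from numba import njit

    _cr72_rates = njit(cache=True, fastmath=False)(_cr72_rates)
    _lm63_rates = njit(cache=True, fastmath=False)(_lm63_rates)
    _it99_rates = njit(cache=True, fastmath=False)(_it99_rates)
    _tsmfk01_rates = njit(cache=True, fastmath=False)(_tsmfk01_rates)
    JITTED = True
except Exception:  # pragma: no cover
    JITTED = False


def cr72_rates(r20: np.ndarray, pA: float, kex: float, dw: np.ndarray, nu: np.ndarray) -> np.ndarray:
    out = np.empty_like(nu)
    _cr72_rates(r20, pA, kex, dw, nu, out)
    return out


def lm63_rates(r20: np.ndarray, phi_ex: np.ndarray, kex: float, nu: np.ndarray) -> np.ndarray:
    out = np.empty_like(nu)
    _lm63_rates(r20, phi_ex, kex, nu, out)
    return out


def it99_rates(r20: np.ndarray, pA: float, kex: float, dw: np.ndarray, nu: np.ndarray) -> np.ndarray:
    out = np.empty_like(nu)
    _it99_rates(r20, pA, kex, dw, nu, out)
    return out


def tsmfk01_rates(r2a0: np.ndarray, k_ab: float, dw: np.ndarray, nu: np.ndarray) -> np.ndarray:
    out = np.empty_like(nu)
    _tsmfk01_rates(r2a0, k_ab, dw, nu, out)
    return out
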