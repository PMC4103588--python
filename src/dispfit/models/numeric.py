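"""Numeric solutions of the two-site Bloch–McConnell equations.

These propagate the magnetization explicitly through the pulse sequence
and serve as the convention-free reference against which the analytic
approximations are validated.

* CPMG SQ — a 2x2 complex evolution matrix over the (A, B) transverse
  magnetizations; 180-degree pulses act as complex conjugation; echo
  pattern (tau - 180 - tau)^n with tau = tau_cp/2 = 1/(4 nu_cpmg).
* MMQ CPMG — the same machinery per coherence; ZQ/DQ evolve with the
  effective shifts dw -/+ dwH; MQ alternates the double- and zero-quantum
  evolution matrices because each refocusing pulse interconverts the two
  coherence components; the two components are propagated in parallel
  and their state-A magnitudes averaged.
* R1rho — a 6x6 real matrix over (x, y, z) x (A, B); a single free
  evolution over the spin-lock period; the rate is the log of the decay
  of the projection onto the state-A effective-field axis.

Exchange rates obey detailed balance: k_AB = pB*kex, k_BA = pA*kex.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.linalg import expm

__all__ = [
    "expm_2x2",
    "build_cpmg_matrix",
    "build_r1rho_matrix",
    "ns_cpmg_2site",
    "ns_mmq_2site",
    "ns_r1rho_2site",
    "NumericalFailure",
]

log = logging.getLogger(__name__)


class NumericalFailure(RuntimeError):
    """Propagation produced a non-positive observable (pathological input)."""


def expm_2x2(m: np.ndarray) -> np.ndarray:
    """Matrix exponential of a 2x2 (complex) matrix in closed form.

    exp(M) = e^mu [cosh(q) I + sinh(q)/q (M - mu I)] with mu = tr(M)/2 and
    q^2 = mu^2 - det(M); the removable q -> 0 singularity is handled by
    the series sinh(q)/q = 1 + q^2/6 + ...
    """
    a, b = m[0, 0], m[0, 1]
    c, d = m[1, 0], m[1, 1]
    mu = 0.5 * (a + d)
    q2 = 0.25 * (a - d) ** 2 + b * c
    q = np.sqrt(complex(q2))
    with np.errstate(over="ignore", invalid="ignore"):
        if abs(q) < 1e-8:
            cosh_q = 1.0 + q2 / 2.0 + q2 * q2 / 24.0
            sinch_q = 1.0 + q2 / 6.0 + q2 * q2 / 120.0
        elif np.real(q) > 300.0:
            # cosh/sinh would overflow; for dissipative matrices the
            # combination exp(mu + q) stays bounded, so evaluate the
            # dominant-branch form directly
            f = 0.5 * np.exp(mu + q)
            half_diff = 0.5 * (a - d)
            return f * np.array(
                [
                    [1.0 + half_diff / q, b / q],
                    [c / q, 1.0 - half_diff / q],
                ]
            )
        else:
            cosh_q = np.cosh(q)
            sinch_q = np.sinh(q) / q
        half_diff = 0.5 * (a - d)
        e = np.exp(mu)
        return e * np.array(
            [
                [cosh_q + sinch_q * half_diff, sinch_q * b],
                [sinch_q * c, cosh_q - sinch_q * half_diff],
            ]
        )


def n_pulses(relax_time: float, nu_cpmg: float) -> int:
    """Number of 180-degree pulses in the constant relaxation period.

    n = 2*T*nu_cpmg rounded to the nearest positive integer; a mismatch of
    more than 1 % between the rounded and exact counts is logged.
    """
    exact = 2.0 * relax_time * nu_cpmg
    n = max(1, int(round(exact)))
    if exact > 0 and abs(n - exact) / exact > 0.01:
        log.warning(
            "nu_cpmg=%g Hz does not fit T=%g s: %g pulses rounded to %d",
            nu_cpmg,
            relax_time,
            exact,
            n,
        )
    return n


def build_cpmg_matrix(
    r20a: float, r20b: float, pA: float, kex: float, dw: float
) -> np.ndarray:
    """2x2 complex evolution matrix for the (A, B) transverse magnetizations.

    dw in rad/s appears as a precession term on state B (state A defines
    the rotating frame).
    """
    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    if kex < 0:
        raise ValueError("kex must be >= 0")
    pB = 1.0 - pA
    k_ab = pB * kex
    k_ba = pA * kex
    return np.array(
        [
            [-r20a - k_ab, k_ba],
            [k_ab, -r20b - k_ba - 1j * dw],
        ],
        dtype=complex,
    )


def _propagate_cpmg(prop: np.ndarray, m0: np.ndarray, n: int) -> np.ndarray:
    """Apply n echo elements (tau - 180 - tau) to m0.

    One element maps m -> P conj(P m); the pulse is complex conjugation.
    """
    m = m0.astype(complex)
    for _ in range(n):
        m = prop @ np.conj(prop @ m)
    return m


def ns_cpmg_2site(
    r20a: float,
    r20b: float,
    pA: float,
    kex: float,
    dw: float,
    nu_cpmg: float,
    relax_time: float,
    segments_per_half_echo: int = 1,
) -> float:
    """Numeric single-quantum CPMG R2eff.

    Starts from thermal equilibrium (pA, pB), applies the echo train and
    extracts R2eff = -ln(Re M_A(T)/pA)/T from the end point, mirroring the
    constant-time experimental observable.  ``segments_per_half_echo``
    exists only to verify that splitting each free-evolution delay changes
    nothing (the matrix exponential is exact per segment).
    """
    n = n_pulses(relax_time, nu_cpmg)
    total_t = relax_time
    tau = total_t / (2.0 * n)  # half-echo delay
    mat = build_cpmg_matrix(r20a, r20b, pA, kex, dw)
    prop = expm_2x2(mat * (tau / segments_per_half_echo))
    prop = np.linalg.matrix_power(prop, segments_per_half_echo)
    m0 = np.array([pA, 1.0 - pA], dtype=complex)
    m = _propagate_cpmg(prop, m0, n)
    ma = float(np.real(m[0]))
    if ma <= 0:
        raise NumericalFailure("state-A magnetization non-positive after the train")
    return -math.log(ma / pA) / total_t


def ns_mmq_2site(
    r20a: float,
    r20b: float,
    pA: float,
    kex: float,
    dw: float,
    dwH: float,
    nu_cpmg: float,
    relax_time: float,
    exp_type: str = "CPMG_SQ",
) -> float:
    """Numeric MMQ CPMG rate for a given coherence.

    SQ is identical to ns_cpmg_2site.  ZQ and DQ evolve like SQ coherence
    at the effective shifts dw - dwH and dw + dwH.  MQ propagates the two
    coherence components in parallel: each starts as DQ or ZQ, and every
    refocusing pulse both conjugates the magnetization and swaps the two
    evolution matrices (the pulse interconverts double- and zero-quantum
    coherence); the state-A magnetizations of the two components are
    averaged.
    """
    if exp_type == "CPMG_SQ":
        return ns_cpmg_2site(r20a, r20b, pA, kex, dw, nu_cpmg, relax_time)
    if exp_type == "CPMG_ZQ":
        return ns_cpmg_2site(r20a, r20b, pA, kex, abs(dw - dwH), nu_cpmg, relax_time)
    if exp_type == "CPMG_DQ":
        return ns_cpmg_2site(r20a, r20b, pA, kex, dw + dwH, nu_cpmg, relax_time)
    if exp_type != "CPMG_MQ":
        raise ValueError(f"unsupported coherence {exp_type!r}")

    # Multiple-quantum propagation per the Korzhnev scheme: the relaxation
    # period holds n_b blocks of duration 1/nu_cpmg, each with two
    # heteronuclear 180s (tau - 180 - 2 tau - 180 - tau, tau = 1/(4 nu));
    # a proton 180 at mid-period moves the coherences into the conjugate
    # space, refocusing the proton shift.  The double- and zero-quantum
    # components (evolution at dw + dwH and dw - dwH) are propagated in
    # parallel and their state-A magnitudes averaged.
    exact = relax_time * nu_cpmg
    n_b = max(1, int(round(exact)))
    if abs(n_b - exact) / exact > 0.01:
        log.warning(
            "nu_cpmg=%g Hz does not fit T=%g s: %g MQ blocks rounded to %d",
            nu_cpmg,
            relax_time,
            exact,
            n_b,
        )
    tau = relax_time / (4.0 * n_b)
    # m1 propagates the I+S+ (double-quantum) component, m2 the I+S-
    # component whose evolution frequency is dwH - dw: a heteronuclear 180
    # flips the sign of dw only, a proton 180 moves both components into
    # the conjugate space.
    m1 = expm_2x2(build_cpmg_matrix(r20a, r20b, pA, kex, dw + dwH) * tau)
    m2 = expm_2x2(build_cpmg_matrix(r20a, r20b, pA, kex, dwH - dw) * tau)
    m1s, m2s = np.conj(m1), np.conj(m2)
    if n_b % 2 == 0:
        half = n_b // 2
        a = np.linalg.matrix_power(m1 @ m2 @ m2 @ m1, half)
        b = np.linalg.matrix_power(m2s @ m1s @ m1s @ m2s, half)
        c = np.linalg.matrix_power(m2 @ m1 @ m1 @ m2, half)
        d = np.linalg.matrix_power(m1s @ m2s @ m2s @ m1s, half)
    else:
        half = (n_b - 1) // 2
        a = np.linalg.matrix_power(m1 @ m2 @ m2 @ m1, half) @ (m1 @ m2)
        b = np.linalg.matrix_power(m2s @ m1s @ m1s @ m2s, half) @ (m2s @ m1s)
        c = np.linalg.matrix_power(m2 @ m1 @ m1 @ m2, half) @ (m2 @ m1)
        d = np.linalg.matrix_power(m1s @ m2s @ m2s @ m1s, half) @ (m1s @ m2s)
    m0 = np.array([pA, 1.0 - pA], dtype=complex)
    m = 0.5 * (a @ (b @ m0) + c @ (d @ m0))
    ma = float(np.real(m[0]))
    if ma <= 0:
        raise NumericalFailure("MQ magnetization non-positive after the train")
    return -math.log(ma / pA) / relax_time


def build_r1rho_matrix(
    r1: float,
    r2a: float,
    r2b: float,
    pA: float,
    kex: float,
    omega_a: float,
    omega_b: float,
    omega1: float,
) -> np.ndarray:
    """6x6 real rotating-frame evolution matrix, basis (xA, yA, zA, xB, yB, zB).

    Per-state blocks describe precession about z at the offset Omega_X and
    nutation about x at omega1 with transverse/longitudinal relaxation;
    exchange couples the states with k_AB = pB*kex, k_BA = pA*kex.
    """
    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    if kex < 0:
        raise ValueError("kex must be >= 0")
    pB = 1.0 - pA
    k_ab = pB * kex
    k_ba = pA * kex

    def block(r2: float, omega: float) -> np.ndarray:
        return np.array(
            [
                [-r2, -omega, 0.0],
                [omega, -r2, -omega1],
                [0.0, omega1, -r1],
            ]
        )

    eye = np.eye(3)
    top = np.hstack([block(r2a, omega_a) - k_ab * eye, k_ba * eye])
    bottom = np.hstack([k_ab * eye, block(r2b, omega_b) - k_ba * eye])
    return np.vstack([top, bottom])


def ns_r1rho_2site(
    r1: float,
    r2a: float,
    r2b: float,
    pA: float,
    kex: float,
    dw: float,
    omega_a: float,
    omega1: float,
    relax_time: float,
    segments: int = 1,
) -> float:
    """Numeric R1rho from free evolution under the spin lock.

    The initial magnetization of both states is aligned with the state-A
    effective field (hard adiabatic alignment); the rate is extracted from
    the decay of the state-A magnetization projected onto that axis:
    R1rho = -ln((v . M_A(T)) / (v . M_A(0))) / T.
    """
    if not (omega1 > 0):
        raise ValueError("omega1 must be positive")
    if not (relax_time > 0):
        raise ValueError("relax_time must be positive")
    omega_b = omega_a + dw
    mat = build_r1rho_matrix(r1, r2a, r2b, pA, kex, omega_a, omega_b, omega1)
    theta_a = math.atan2(omega1, omega_a)
    v = np.array([math.sin(theta_a), 0.0, math.cos(theta_a)])
    m0 = np.concatenate([pA * v, (1.0 - pA) * v])
    prop = expm(mat * (relax_time / segments))
    m = m0
    for _ in range(segments):
        m = prop @ m
    proj = float(v @ m[:3])
    proj0 = pA
    if proj <= 0:
        raise NumericalFailure("projection non-positive after the spin lock")
    return -math.log(proj / proj0) / relax_time
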