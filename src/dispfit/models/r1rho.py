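"""Closed-form R1rho models for two-site exchange under a spin lock.

The shared geometry is the effective field in the rotating frame: a
spin-lock of angular amplitude omega1 applied at offset Omega from the
(population-averaged) resonance gives an effective field of squared
magnitude omega_eff^2 = Omega^2 + omega1^2 tilted by theta =
atan2(omega1, Omega) from the z axis.

Models:

* No Rex — rotating-frame baseline R1 cos^2(theta) + R1rho' sin^2(theta).
* M61 — Meiboom fast-exchange, on-resonance.
* DPL94 — Davis–Perlman–London extension of M61 to off-resonance data.
* TP02 — Trott–Palmer non-fast-exchange model (skewed populations).
* MP05 — Miloushev–Palmer second-order correction of TP02.

All angular frequencies in rad/s; rates in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SpinLockGeometry",
    "spin_lock_geometry",
    "r1rho_norex",
    "r1rho_m61",
    "r1rho_dpl94",
    "r1rho_tp02",
    "r1rho_mp05",
]


@dataclass(frozen=True)
class SpinLockGeometry:
    """Derived rotating-frame geometry shared by all R1rho models.

    omega1, offsets in rad/s.  Omega_A is the state-A resonance offset from
    the spin-lock carrier; Omega_B = Omega_A + dw; Omega_avg is the
    population average.  theta is the effective-field tilt angle from the
    average offset, in (0, pi).
    """

    omega1: float
    omega_a: float
    omega_b: float
    omega_avg: float
    theta: float
    omega_eff_sq: float


def spin_lock_geometry(
    omega1: float, omega_a: float, dw: float, pA: float
) -> SpinLockGeometry:
    """Build the spin-lock geometry for one condition.

    Parameters are the spin-lock amplitude omega1 (rad/s), the state-A
    offset from the carrier Omega_A (rad/s, signed), the shift difference
    dw (rad/s, magnitude; state B sits at Omega_A + dw) and the state-A
    population.
    """
    if not (omega1 > 0):
        raise ValueError("omega1 must be positive")
    omega_b = omega_a + dw
    omega_avg = pA * omega_a + (1.0 - pA) * omega_b
    theta = math.atan2(omega1, omega_avg)
    return SpinLockGeometry(
        omega1=omega1,
        omega_a=omega_a,
        omega_b=omega_b,
        omega_avg=omega_avg,
        theta=theta,
        omega_eff_sq=omega_avg * omega_avg + omega1 * omega1,
    )


def r1rho_norex(r1: float, r1rho_prime: float, geom: SpinLockGeometry) -> float:
    """Exchange-free rotating-frame rate R1 cos^2(theta) + R1rho' sin^2(theta)."""
    c = math.cos(geom.theta)
    s = math.sin(geom.theta)
    return r1 * c * c + r1rho_prime * s * s


def r1rho_m61(
    r1rho_prime: float, phi_ex: float, kex: float, geom: SpinLockGeometry
) -> float:
    """Meiboom fast-exchange model for on-resonance data.

    R1rho = R1rho' + phi_ex*kex/(kex^2 + omega1^2).  phi_ex in rad^2/s^2.
    """
    if phi_ex < 0:
        raise ValueError("phi_ex must be >= 0")
    if phi_ex == 0.0:
        return float(r1rho_prime)
    if kex <= 0:
        raise ValueError("M61 requires kex > 0 when phi_ex > 0")
    return r1rho_prime + phi_ex * kex / (kex * kex + geom.omega1 * geom.omega1)


def r1rho_dpl94(
    r1: float,
    r1rho_prime: float,
    phi_ex: float,
    kex: float,
    geom: SpinLockGeometry,
) -> float:
    """Davis–Perlman–London off-resonance fast-exchange model.

    R1rho = R1 cos^2(theta) + sin^2(theta) * [R1rho' +
    phi_ex*kex/(kex^2 + omega_eff^2)].  Reduces to M61 on resonance.
    """
    if phi_ex < 0:
        raise ValueError("phi_ex must be >= 0")
    c = math.cos(geom.theta)
    s = math.sin(geom.theta)
    base = r1 * c * c + r1rho_prime * s * s
    if phi_ex == 0.0:
        return base
    if kex <= 0:
        raise ValueError("DPL94 requires kex > 0 when phi_ex > 0")
    return base + s * s * (phi_ex * kex / (kex * kex + geom.omega_eff_sq))


def r1rho_tp02(
    r1: float,
    r1rho_prime: float,
    pA: float,
    kex: float,
    dw: float,
    geom: SpinLockGeometry,
) -> float:
    """Trott–Palmer model for skewed-population, non-fast exchange.

    R1rho = R1 cos^2 + R1rho' sin^2 + sin^2 * pA*pB*dw^2*kex /
    (wA_eff^2 * wB_eff^2 / w_eff^2 + kex^2), with the state-specific
    effective fields wX_eff^2 = Omega_X^2 + omega1^2.
    """
    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    c = math.cos(geom.theta)
    s = math.sin(geom.theta)
    base = r1 * c * c + r1rho_prime * s * s
    if pA == 1.0 or dw == 0.0 or kex == 0.0:
        return base
    pB = 1.0 - pA
    wa2 = geom.omega_a * geom.omega_a + geom.omega1 * geom.omega1
    wb2 = geom.omega_b * geom.omega_b + geom.omega1 * geom.omega1
    denom = wa2 * wb2 / geom.omega_eff_sq + kex * kex
    return base + s * s * pA * pB * dw * dw * kex / denom


def r1rho_mp05(
    r1: float,
    r1rho_prime: float,
    pA: float,
    kex: float,
    dw: float,
    geom: SpinLockGeometry,
) -> float:
    """Miloushev–Palmer model: TP02 with a second-order denominator term.

    The correction subtracts sin^2(theta)*pA*pB*dw^2 * [1 +
    2 kex^2 (pA wA_eff^2 + pB wB_eff^2) / (wA_eff^2 wB_eff^2 +
    w_eff^2 kex^2)] from the TP02 denominator, extending validity beyond
    strongly skewed populations.
    """
    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    c = math.cos(geom.theta)
    s = math.sin(geom.theta)
    base = r1 * c * c + r1rho_prime * s * s
    if pA == 1.0 or dw == 0.0 or kex == 0.0:
        return base
    pB = 1.0 - pA
    s2 = s * s
    dw2 = dw * dw
    wa2 = geom.omega_a * geom.omega_a + geom.omega1 * geom.omega1
    wb2 = geom.omega_b * geom.omega_b + geom.omega1 * geom.omega1
    kex2 = kex * kex
    correction = s2 * pA * pB * dw2 * (
        1.0 + 2.0 * kex2 * (pA * wa2 + pB * wb2) / (wa2 * wb2 + geom.omega_eff_sq * kex2)
    )
    denom = wa2 * wb2 / geom.omega_eff_sq + kex2 - correction
    return base + s2 * pA * pB * dw2 * kex / denom
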