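"""Closed-form R2eff(nu_cpmg) for two-site exchange CPMG experiments.

Models, from simple to complex:

* No Rex — a flat dispersion, R2eff = R2(0) at every pulse-train frequency.
* LM63 — Luz–Meiboom fast exchange, parameterised by phi_ex = pA*pB*dw^2.
* CR72 — the Carver–Richards general two-site closed form.
* IT99 — Ishima–Torchia population-skewed approximation.
* TSMFK01 — Tollinger et al. very-slow-exchange (forward-rate) model.
* MMQ CR72 — the Korzhnev multiple-quantum extension of CR72, covering
  SQ/ZQ/DQ/MQ coherences with both the heteronuclear (dw) and the proton
  (dwH) shift differences.

All kernels take angular shift differences in rad/s and the CPMG
pulse-train frequency nu_cpmg in Hz, are vectorised over nu_cpmg, and
return R2eff in 1/s.  The convention used throughout: tau_cp is the delay
between consecutive 180-degree pulses and nu_cpmg = 1/(2*tau_cp).

Every model returns the exchange-free baseline exactly when exchange
vanishes (pA = 1, dw = 0, phi_ex = 0 or k_AB = 0); these branches are
explicit so the identity holds at machine precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "r2eff_norex",
    "r2eff_lm63",
    "r2eff_cr72",
    "r2eff_it99",
    "r2eff_tsmfk01",
    "r2eff_mmq_cr72",
]

_ETA_SCALE = 1.0 / (2.0 * np.sqrt(2.0))  # 2^(-3/2)


def _as_array(nu_cpmg) -> np.ndarray:
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    return nu


def r2eff_norex(r20: float, nu_cpmg) -> np.ndarray:
    """Flat dispersion: the baseline rate at every pulse-train frequency."""
    nu = _as_array(nu_cpmg)
    return np.full_like(nu, float(r20))


def r2eff_lm63(r20: float, phi_ex: float, kex: float, nu_cpmg) -> np.ndarray:
    """Luz–Meiboom fast-exchange model.

    R2eff = R2(0) + (phi_ex/kex) * [1 - (4 nu/kex) tanh(kex/(4 nu))],
    with phi_ex = pA*pB*dw^2 in rad^2/s^2.
    """
    nu = _as_array(nu_cpmg)
    phi_ex = np.asarray(phi_ex, dtype=float)
    if np.any(phi_ex < 0):
        raise ValueError("phi_ex must be >= 0")
    if np.all(phi_ex == 0.0):
        return np.broadcast_to(np.asarray(r20, float), nu.shape).astype(float)
    if kex <= 0:
        raise ValueError("LM63 requires kex > 0 when phi_ex > 0")
    x = kex / (4.0 * nu)
    return r20 + (phi_ex / kex) * (1.0 - np.tanh(x) / x)


def r2eff_cr72(
    r20a: float,
    r20b: float,
    pA: float,
    kex: float,
    dw: float,
    nu_cpmg,
) -> np.ndarray:
    """Carver–Richards closed form for two-site exchange.

    dw is the angular shift difference in rad/s.  The arccosh argument is
    clamped to >= 1 to guard against rounding for vanishing exchange.
    """
    nu = _as_array(nu_cpmg)
    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    if kex < 0 or np.any(np.asarray(dw) < 0):
        raise ValueError("kex and dw must be >= 0")
    dw = np.asarray(dw, dtype=float)
    r20a = np.asarray(r20a, dtype=float)
    r20b = np.asarray(r20b, dtype=float)
    if pA == 1.0 or kex == 0.0 or np.all(dw == 0.0):
        # no observable exchange: population-A baseline
        base = r20a if pA == 1.0 else 0.5 * (r20a + r20b)
        return np.broadcast_to(base, nu.shape).copy() if base.ndim else np.full_like(nu, float(base))

    pB = 1.0 - pA
    dw2 = dw * dw
    fact = r20a - r20b - pA * kex + pB * kex
    psi = fact * fact - dw2 + 4.0 * pA * pB * kex * kex
    zeta = 2.0 * dw * fact
    root = np.hypot(psi, zeta)
    d_common = (psi + 2.0 * dw2) / root
    d_pos = 0.5 * (1.0 + d_common)
    d_neg = 0.5 * (-1.0 + d_common)
    eta_pos = _ETA_SCALE * np.sqrt(np.maximum(psi + root, 0.0)) / nu
    eta_neg = _ETA_SCALE * np.sqrt(np.maximum(root - psi, 0.0)) / nu
    # For large eta_pos the cosh term overflows; there arccosh(arg) ->
    # eta_pos + ln(d_pos) exactly to double precision.
    with np.errstate(over="ignore", invalid="ignore"):
        arg = d_pos * np.cosh(eta_pos) - d_neg * np.cos(eta_neg)
        direct = np.arccosh(np.maximum(arg, 1.0))
    asymptotic = eta_pos + np.log(np.maximum(d_pos, 1e-300))
    acosh_term = np.where(eta_pos > 300.0, asymptotic, direct)
    out = 0.5 * (r20a + r20b + kex) - nu * acosh_term
    if np.any(dw == 0.0):
        # per-point vanishing exchange must return the baseline exactly
        out = np.where(dw == 0.0, 0.5 * (r20a + r20b), out)
    return out


def r2eff_it99(
    r20: float, pA: float, kex: float, dw: float, nu_cpmg
) -> np.ndarray:
    """Ishima–Torchia population-skewed approximation.

    R2eff = R2(0) + pA*pB*dw^2*kex / (kex^2 + sqrt(pA^2 dw^4 + 144/tau_cp^4)),
    with tau_cp = 1/(2 nu_cpmg).  Valid for skewed populations (pA >> pB)
    over all time scales.
    """
    nu = _as_array(nu_cpmg)
    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    dw = np.asarray(dw, dtype=float)
    if kex < 0 or np.any(dw < 0):
        raise ValueError("kex and dw must be >= 0")
    if pA == 1.0 or kex == 0.0 or np.all(dw == 0.0):
        return np.broadcast_to(np.asarray(r20, float), nu.shape).astype(float)
    pB = 1.0 - pA
    tcp = 1.0 / (2.0 * nu)
    denom = kex * kex + np.sqrt(pA * pA * dw**4 + 144.0 / tcp**4)
    return r20 + pA * pB * dw * dw * kex / denom


def r2eff_tsmfk01(r2a0: float, k_ab: float, dw: float, nu_cpmg) -> np.ndarray:
    """Tollinger et al. very-slow-exchange model for the state-A resonance.

    R2eff = R2A(0) + k_AB - k_AB * sinc(dw * tau_cp), tau_cp = 1/(2 nu).
    Only the forward rate A->B enters; the model describes the initial-rate
    loss of state-A magnetization when back-transfer is negligible.
    """
    nu = _as_array(nu_cpmg)
    dw = np.asarray(dw, dtype=float)
    if k_ab < 0 or np.any(dw < 0):
        raise ValueError("k_AB and dw must be >= 0")
    if k_ab == 0.0 or np.all(dw == 0.0):
        return np.broadcast_to(np.asarray(r2a0, float), nu.shape).astype(float)
    x = dw / (2.0 * nu)  # dw * tau_cp
    # np.sinc is sin(pi x)/(pi x); series-safe for small x by construction
    return r2a0 + k_ab - k_ab * np.sinc(x / np.pi)


def r2eff_mmq_cr72(
    r20a: float,
    r20b: float,
    pA: float,
    kex: float,
    dw: float,
    dwH: float,
    nu_cpmg,
    exp_type: str = "CPMG_SQ",
) -> np.ndarray:
    """Korzhnev multiple-quantum extension of the Carver–Richards form.

    Coherence handling: SQ uses dw alone; ZQ and DQ use the effective
    shifts |dw - dwH| and dw + dwH in the real CR72 expression; MQ uses the
    complex generalisation in which the proton shift enters the Psi/zeta
    terms as an imaginary frequency and the real part of the resulting
    rate is returned.
    """
    nu = _as_array(nu_cpmg)
    if exp_type == "CPMG_SQ":
        return r2eff_cr72(r20a, r20b, pA, kex, dw, nu)
    if exp_type == "CPMG_ZQ":
        return r2eff_cr72(r20a, r20b, pA, kex, abs(dw - dwH), nu)
    if exp_type == "CPMG_DQ":
        return r2eff_cr72(r20a, r20b, pA, kex, dw + dwH, nu)
    if exp_type != "CPMG_MQ":
        raise ValueError(f"unsupported coherence {exp_type!r}")

    if not (0.5 <= pA <= 1.0):
        raise ValueError("pA must lie in [0.5, 1]")
    if pA == 1.0 or kex == 0.0 or (dw == 0.0 and dwH == 0.0):
        return np.full_like(nu, float(r20a) if pA == 1.0 else 0.5 * (r20a + r20b))

    pB = 1.0 - pA
    k_ab = pB * kex
    k_ba = pA * kex
    dw2 = dw * dw
    fact = 1j * dwH + (k_ba - k_ab) + (r20a - r20b)
    psi = fact * fact - dw2 + 4.0 * k_ab * k_ba
    zeta = -2.0 * dw * fact
    root = np.sqrt(psi * psi + zeta * zeta)
    d_common = (psi + 2.0 * dw2) / root
    d_pos = 0.5 * (1.0 + d_common)
    d_neg = 0.5 * (-1.0 + d_common)
    eta_pos = _ETA_SCALE * np.sqrt(psi + root) / nu
    eta_neg = _ETA_SCALE * np.sqrt(root - psi) / nu
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        arg = d_pos * np.cosh(eta_pos) - d_neg * np.cos(eta_neg)
        direct = np.arccosh(arg.astype(complex))
        asymptotic = eta_pos + np.log(d_pos + 0j)
        acosh_term = np.where(np.real(eta_pos) > 300.0, asymptotic, direct)
    rate = 0.5 * (r20a + r20b + kex) - nu * acosh_term
    return np.real(rate)
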