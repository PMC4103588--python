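"""Unit conversions between spectroscopist-facing and internal units.

All model kernels work in angular frequencies (rad/s); users supply chemical
shifts and shift differences in ppm, CPMG pulse-train frequencies and
spin-lock amplitudes in Hz, and rates in 1/s.  This module is the single
conversion boundary.
"""

from __future__ import annotations

import math

__all__ = [
    "GYROMAGNETIC_RATIO",
    "ppm_to_rad_per_s",
    "offset_ppm_to_rad_per_s",
    "hz_to_rad_per_s",
]

#: Magnitude of the gyromagnetic ratio of each supported isotope relative to
#: the proton, |gamma_X / gamma_1H|.
GYROMAGNETIC_RATIO: dict[str, float] = {
    "1H": 1.0,
    "15N": 0.10136767,
    "13C": 0.25144953,
}


class UnknownIsotopeError(KeyError):
    """Raised when an isotope has no gyromagnetic-ratio entry."""


def ppm_to_rad_per_s(delta_ppm: float, field_h1_mhz: float, isotope: str) -> float:
    """Convert a chemical-shift difference in ppm to an angular frequency.

    The static field is given as the proton Larmor frequency in MHz, so for
    isotope X the Larmor frequency is ``field_h1_mhz * |gamma_X/gamma_1H|``
    MHz and one ppm corresponds to that many Hz.  The magnitude is returned:
    the sign of a shift difference is not determinable from dispersion data
    alone (all two-site models depend on it only through even powers or a
    global symmetry).

    Returns
    -------
    float
        ``|delta_ppm| * 2*pi * field_h1_mhz * |gamma_X/gamma_1H|`` in rad/s.
    """
    try:
        ratio = GYROMAGNETIC_RATIO[isotope]
    except KeyError:
        raise UnknownIsotopeError(
            f"isotope {isotope!r} has no gyromagnetic-ratio entry; "
            f"known: {sorted(GYROMAGNETIC_RATIO)}"
        ) from None
    return abs(delta_ppm) * 2.0 * math.pi * field_h1_mhz * ratio


def offset_ppm_to_rad_per_s(offset_ppm: float, field_h1_mhz: float, isotope: str) -> float:
    """Signed ppm-to-rad/s conversion for spin-lock carrier offsets.

    Unlike a shift *difference* between exchanging states, the offset of a
    resonance from the spin-lock carrier is a signed quantity and its sign
    matters for the tilt-angle geometry.
    """
    try:
        ratio = GYROMAGNETIC_RATIO[isotope]
    except KeyError:
        raise UnknownIsotopeError(
            f"isotope {isotope!r} has no gyromagnetic-ratio entry; "
            f"known: {sorted(GYROMAGNETIC_RATIO)}"
        ) from None
    return offset_ppm * 2.0 * math.pi * field_h1_mhz * ratio


def hz_to_rad_per_s(nu_hz: float) -> float:
    """Convert an ordinary frequency in Hz to rad/s."""
    return 2.0 * math.pi * nu_hz
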