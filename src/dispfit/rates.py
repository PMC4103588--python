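"""Conversion of peak intensities to effective relaxation rates.

Two conversions are supported, chosen by the experiment design:

* constant-time experiments — the two-point log ratio
  ``R2eff = -ln(I / I_ref) / T`` against a reference spectrum recorded
  without the relaxation period;
* non-constant-time experiments — a weighted least-squares fit of a
  two-parameter exponential ``I(t) = I0 * exp(-R t)`` over several
  relaxation delays.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .data import RateValue

__all__ = [
    "calc_r2eff_two_point",
    "propagate_r2eff_error",
    "calc_r2eff_exponential_free",
]

log = logging.getLogger(__name__)


def calc_r2eff_two_point(i_ref: float, i: float, relax_time: float) -> float:
    """Constant-time R2eff from a single intensity ratio.

    Negative rates (intensity above the reference) are allowed — they occur
    for noisy flat dispersions — and are flagged in the log.
    """
    if not (i_ref > 0 and i > 0):
        raise ValueError("intensities must be positive")
    if not (relax_time > 0):
        raise ValueError("relaxation period must be positive")
    rate = -math.log(i / i_ref) / relax_time
    if rate < 0:
        log.warning("negative R2eff %.4g 1/s (I > I_ref)", rate)
    return rate


def propagate_r2eff_error(
    i_ref: float, i: float, sigma_ref: float, sigma: float, relax_time: float
) -> float:
    """First-order error propagation for the two-point conversion.

    sigma_R = sqrt((sigma/I)^2 + (sigma_ref/I_ref)^2) / T.
    """
    if not (i_ref > 0 and i > 0):
        raise ValueError("intensities must be positive")
    if relax_time == 0:
        raise ValueError("relaxation period must be non-zero")
    if sigma_ref < 0 or sigma < 0:
        raise ValueError("intensity errors must be >= 0")
    return math.hypot(sigma / i, sigma_ref / i_ref) / relax_time


def calc_r2eff_exponential_free(
    intensity_by_time: dict[float, tuple[float, float]],
) -> RateValue:
    """Weighted least-squares fit of I(t) = I0 * exp(-R t).

    Linearised as ln I = ln I0 - R t with weights I^2/sigma^2 (delta-method
    variance of ln I), which is the standard generalised-least-squares
    treatment of a single-exponential decay.  Returns the rate and its
    covariance-based one-sigma error.
    """
    if len(intensity_by_time) < 2:
        raise ValueError("need at least two time points")
    times = np.array(sorted(intensity_by_time), dtype=float)
    ints = np.array([intensity_by_time[t][0] for t in times])
    sigs = np.array([intensity_by_time[t][1] for t in times])
    if np.any(ints <= 0):
        raise ValueError("intensities must be positive")
    if np.ptp(times) == 0:
        raise ValueError("degenerate design: all time points equal")
    y = np.log(ints)
    # weights: var(ln I) = (sigma/I)^2; zero-noise points get unit weight
    var = np.where(sigs > 0, (sigs / ints) ** 2, 1.0)
    w = 1.0 / var
    X = np.column_stack([np.ones_like(times), -times])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    rate = float(beta[1])
    err = float(math.sqrt(max(cov[1, 1], 0.0))) if np.any(sigs > 0) else 0.0
    return RateValue(value=rate, error=err)
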