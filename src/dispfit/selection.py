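"""Model elimination, Monte Carlo error propagation and AIC selection.

For Gaussian errors chi2 is -2 log-likelihood up to a constant, so models
are ranked per cluster by AIC = chi2 + 2k.  Before ranking, fixed
elimination rules remove failed fits (kinetics pushed to the parameter
bounds, non-convergence, non-finite values); the no-exchange model is
never eliminated so a candidate always remains.  Parameter errors come
from Monte Carlo simulation: noise-perturbed synthetic datasets are
refitted from the point estimate and the surviving spread is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .data import RateValue
from .fitting import FitResult, Objective, minimise
from .catalog import CATALOG_ORDER

__all__ = [
    "aic",
    "EliminationRules",
    "eliminate",
    "monte_carlo_errors",
    "SelectionOutcome",
    "select_model",
    "ErrorEstimationFailure",
]


def aic(chi2: float, k: int) -> float:
    """Akaike's Information Criterion, chi2 + 2k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return chi2 + 2.0 * k


@dataclass(frozen=True)
class EliminationRules:
    """Thresholds for the fixed model-elimination rules.

    A fit is eliminated when (a) kex sits within ``kex_bound_frac`` of its
    upper bound, (b) pA is within ``pa_tol`` of 1 while dw sits at its
    upper bound (exchange pushed outside the observable window), (c) the
    optimizer did not converge, or (d) any parameter is non-finite.
    """

    kex_bound_frac: float = 0.01
    pa_tol: float = 1e-4
    dw_bound_frac: float = 0.01


def eliminate(fit: FitResult, rules: EliminationRules = EliminationRules()) -> tuple[bool, str | None]:
    """Apply the fixed elimination rules to one fit: (flag, reason)."""
    pv = fit.params
    if not np.all(np.isfinite(pv.values)):
        return True, "non-finite parameter value"
    if not fit.converged:
        return True, "optimization did not converge"
    pa_near_one = False
    dw_at_bound = False
    for key, val, hi in zip(pv.keys, pv.values, pv.upper):
        if key.symbol in ("kex", "k_ab") and val >= (1.0 - rules.kex_bound_frac) * hi:
            return True, f"{key.symbol} within {rules.kex_bound_frac:.0%} of its upper bound"
        if key.symbol == "pA" and val >= 1.0 - rules.pa_tol:
            pa_near_one = True
        if key.symbol in ("dw", "dwH") and val >= (1.0 - rules.dw_bound_frac) * hi:
            dw_at_bound = True
    if pa_near_one and dw_at_bound:
        return True, "pA at 1 with dw at its upper bound"
    return False, None


class ErrorEstimationFailure(RuntimeError):
    """All Monte Carlo simulations were eliminated."""


def monte_carlo_errors(
    fit: FitResult,
    objective: Objective,
    n_sims: int,
    seed: int,
    rules: EliminationRules = EliminationRules(),
    fatol: float = 1e-25,
    xatol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[dict[str, float], int]:
    """Monte Carlo error propagation for one fit.

    Each simulation back-calculates rates from the fitted parameters, adds
    Gaussian noise with the measured per-point sigma, refits starting from
    the point estimate (the grid is skipped, mirroring the warm-start
    philosophy), and applies the elimination rules.  Returns per-parameter
    standard deviations over the surviving simulations and the count of
    removed ones.  Simulation i uses the deterministic seed (seed, i), so
    parallel and serial execution agree bit for bit.
    """
    if n_sims < 2:
        raise ValueError("need at least two simulations")
    calc = objective.back_calc(fit.params.values)
    base = objective.dataset
    samples: list[np.ndarray] = []
    removed = 0
    for i in range(n_sims):
        rng = np.random.default_rng([seed, i])
        values: dict[tuple[str, int], RateValue] = {}
        for sid in objective.spin_ids:
            rates = calc[sid]
            for j, (idx, _, rv) in enumerate(base.iter_spin_values(sid)):
                noisy = rates[j] + (rng.normal(0.0, rv.error) if rv.error > 1e-12 else 0.0)
                values[(sid, idx)] = RateValue(float(noisy), rv.error)
        # keep spins outside the cluster untouched so dataset invariants hold
        for (sid, idx), rv in base.values.items():
            values.setdefault((sid, idx), rv)
        sim_dataset = base.with_values(values)
        sim_obj = Objective(objective.model, sim_dataset, objective.spin_ids)
        sim_fit = minimise(
            sim_obj,
            fit.params.values.copy(),
            fatol=fatol,
            xatol=xatol,
            max_iter=max_iter,
            warm_start_source="mc-point-estimate",
        )
        flag, _ = eliminate(sim_fit, rules)
        if flag:
            removed += 1
        else:
            samples.append(sim_fit.params.values.copy())
    if not samples:
        raise ErrorEstimationFailure(
            f"all {n_sims} Monte Carlo simulations were eliminated"
        )
    arr = np.array(samples)
    sd = arr.std(axis=0, ddof=1) if len(samples) > 1 else np.zeros(arr.shape[1])
    return {str(k): float(s) for k, s in zip(fit.params.keys, sd)}, removed


@dataclass
class SelectionOutcome:
    """AIC ranking of the candidate models for one cluster."""

    ranked: list[tuple[str, float]]  # (model, aic) over non-eliminated fits
    chosen: str
    elimination_log: list[tuple[str, str]] = dc_field(default_factory=list)


def select_model(results: dict[str, FitResult]) -> SelectionOutcome:
    """Choose the model with minimal AIC among non-eliminated fits.

    The no-exchange model is always a candidate even if flagged.  Ties
    break to the model with fewer parameters, then to catalogue order.
    """
    if not results:
        raise ValueError("no fit results to select from")
    elim_log = [
        (name, fit.elimination_reason or "eliminated")
        for name, fit in results.items()
        if fit.eliminated and name != "NoRex"
    ]
    candidates = {
        name: fit
        for name, fit in results.items()
        if not fit.eliminated or name == "NoRex"
    }
    if not candidates:
        raise ValueError("every candidate model was eliminated")
    ranked = sorted(
        ((name, fit.aic) for name, fit in candidates.items()),
        key=lambda item: (
            item[1],
            candidates[item[0]].k,
            CATALOG_ORDER.get(item[0], len(CATALOG_ORDER)),
        ),
    )
    return SelectionOutcome(ranked=ranked, chosen=ranked[0][0], elimination_log=elim_log)
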