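"""The automated analysis protocol.

Stages: (1) a non-clustered pass fitting every applicable model to every
spin in catalogue order, each model warm-started per the fixed
nesting/equivalence table (grid searched only where the table says so);
(2) fixed-rule elimination; (3) for defined clusters, a clustered pass
seeded by averaging the non-clustered optima; (4) Monte Carlo error
propagation for the surviving fits; (5) a final AIC model-selection run
over the stored fits (re-evaluation, not refitting).

Work is partitioned at the spin/cluster level and, through per-simulation
seeds, at the Monte Carlo level; results are assembled in a fixed order,
so any worker count yields a bit-identical report.
"""

from __future__ import annotations

import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field as dc_field

from .catalog import MODEL_CATALOG, get_model, list_models  # noqa: F401  (re-export)
from .data import DispersionDataset
from .fitting import (
    FitResult,
    Objective,
    cluster_average_start,
    minimise,
    warm_start,
)
from .selection import (
    EliminationRules,
    ErrorEstimationFailure,
    SelectionOutcome,
    eliminate,
    monte_carlo_errors,
    select_model,
)

__all__ = [
    "ProtocolConfig",
    "ProtocolReport",
    "run_protocol",
    "parallel_map",
    "list_models",
]

DEFAULT_MODELS = [m.name for m in MODEL_CATALOG]


@dataclass
class ProtocolConfig:
    """Settings of one automated analysis run.

    The model list keeps catalogue order and must start with the
    no-exchange model; the seed is mandatory.  ``clusters`` maps
    cluster_id -> spin ids (clusters defined on the dataset's spins are
    merged in automatically).
    """

    seed: int
    models: list[str] = dc_field(default_factory=lambda: list(DEFAULT_MODELS))
    clusters: dict[str, list[str]] = dc_field(default_factory=dict)
    grid_points: int = 11
    fatol: float = 1e-25
    xatol: float = 1e-10
    max_iter: int = 2000
    n_sims: int = 500
    mc_enabled: bool = True
    workers: int = 1
    elimination: EliminationRules = dc_field(default_factory=EliminationRules)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be non-empty")
        if self.models[0] != "NoRex":
            raise ValueError("model list must start with NoRex")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        order = {m.name: i for i, m in enumerate(MODEL_CATALOG)}
        self.models = sorted(self.models, key=lambda n: order[n])


@dataclass
class ProtocolReport:
    """Everything the protocol produced, keyed by work unit.

    Work units are "spin:<id>" for single-spin fits and "cluster:<id>"
    for clustered fits.  ``fits`` holds one FitResult per (unit, model)
    pair that ran; ``skipped`` records the pairs that could not run and
    why, so every pair is accounted for.
    """

    config_snapshot: dict
    fits: dict[tuple[str, str], FitResult] = dc_field(default_factory=dict)
    skipped: dict[tuple[str, str], str] = dc_field(default_factory=dict)
    outcomes: dict[str, SelectionOutcome] = dc_field(default_factory=dict)
    curves: dict[str, list[dict]] = dc_field(default_factory=dict)
    log_lines: list[str] = dc_field(default_factory=list)
    spin_unit: dict[str, str] = dc_field(default_factory=dict)

    def chosen_model(self, spin_id: str) -> str:
        return self.outcomes[self.spin_unit[spin_id]].chosen

    def summary_rows(self) -> list[dict]:
        rows = []
        for (unit, model), fit in sorted(self.fits.items()):
            chosen = self.outcomes[unit].chosen if unit in self.outcomes else None
            row = {
                "spin_id": ",".join(fit.spin_ids),
                "cluster_id": unit,
                "model": model,
                "chosen": model == chosen,
                "chi2": fit.chi2,
                "k": fit.k,
                "n": fit.n,
                "aic": fit.aic,
                "eliminated": fit.eliminated,
                "elimination_reason": fit.elimination_reason,
                "warm_start_source": fit.warm_start_source,
            }
            for key, val in fit.params.as_dict().items():
                row[f"param:{key}"] = val
            for key, val in fit.mc_errors.items():
                row[f"error:{key}"] = val
            rows.append(row)
        return rows


def parallel_map(func, units: list, workers: int = 1) -> list:
    """Order-preserving map over independent work units.

    With one worker the map is serial.  With more, units run in a process
    pool; a unit whose worker fails is retried serially and the failure
    recorded by the caller.  Results are returned in input order whatever
    the worker count.
    """
    if workers <= 1 or len(units) <= 1:
        return [func(u) for u in units]
    results = [None] * len(units)
    with ProcessPoolExecutor(max_workers=workers) as pool:
        futures = [pool.submit(func, u) for u in units]
        for i, fut in enumerate(futures):
            try:
                results[i] = fut.result()
            except Exception:
                results[i] = func(units[i])  # serial retry
    return results


def _applicable(model_name: str, dataset: DispersionDataset, spin_ids: list[str]) -> str | None:
    """None if the model can describe every point of the spins, else why not."""
    model = get_model(model_name)
    types = {
        dataset.points[i].exp_type for sid in spin_ids for i in dataset.point_indices(sid)
    }
    bad = sorted(t for t in types if not model.supports(t))
    if bad:
        return f"unsupported experiment types: {bad}"
    if model_name in ("MMQ_CR72", "NS_MMQ_2site") and types == {"CPMG_SQ"}:
        return "only SQ data present; the SQ analytic/numeric models cover it"
    if model.kind == "r1rho" and model_name != "M61":
        for sid in spin_ids:
            for i in dataset.point_indices(sid):
                if dataset.points[i].r1 is None:
                    return "off-resonance R1rho models need a measured R1"
    return None


def _fit_unit(args) -> tuple[str, dict, dict, list[str]]:
    """Worker: fit all applicable models to one spin (non-clustered pass)."""
    dataset, config, sid = args
    unit = f"spin:{sid}"
    fits: dict[str, FitResult] = {}
    skipped: dict[str, str] = {}
    log: list[str] = []
    for name in config.models:
        reason = _applicable(name, dataset, [sid])
        if reason is not None:
            skipped[name] = reason
            continue
        obj = Objective(name, dataset, [sid])
        start, source = warm_start(obj, fits, config.grid_points)
        fit = minimise(
            obj,
            start,
            fatol=config.fatol,
            xatol=config.xatol,
            max_iter=config.max_iter,
            warm_start_source=source,
        )
        fit.eliminated, fit.elimination_reason = eliminate(fit, config.elimination)
        fits[name] = fit
        log.append(
            f"{unit} {name}: chi2={fit.chi2:.6g} aic={fit.aic:.6g} "
            f"start={source} eliminated={fit.eliminated}"
        )
    return unit, fits, skipped, log


def _fit_cluster_unit(args) -> tuple[str, dict, dict, list[str]]:
    """Worker: clustered pass for one cluster, averaged warm starts."""
    dataset, config, cid, members, spin_results = args
    unit = f"cluster:{cid}"
    fits: dict[str, FitResult] = {}
    skipped: dict[str, str] = {}
    log: list[str] = []
    for name in config.models:
        reason = _applicable(name, dataset, members)
        if reason is not None:
            skipped[name] = reason
            continue
        missing = [sid for sid in members if name not in spin_results.get(sid, {})]
        if missing:
            skipped[name] = f"no non-clustered result for {missing}"
            continue
        obj = Objective(name, dataset, members)
        start = cluster_average_start(
            {sid: spin_results[sid][name] for sid in members}, obj
        )
        fit = minimise(
            obj,
            start,
            fatol=config.fatol,
            xatol=config.xatol,
            max_iter=config.max_iter,
            warm_start_source="cluster-average",
        )
        fit.eliminated, fit.elimination_reason = eliminate(fit, config.elimination)
        fits[name] = fit
        log.append(
            f"{unit} {name}: chi2={fit.chi2:.6g} aic={fit.aic:.6g} "
            f"start=cluster-average eliminated={fit.eliminated}"
        )
    return unit, fits, skipped, log


def _mc_unit(args) -> tuple[str, str, dict, int, str | None]:
    """Worker: Monte Carlo errors for one (unit, model) fit."""
    dataset, config, unit, name, fit, seed = args
    obj = Objective(name, dataset, list(fit.spin_ids))
    try:
        errors, removed = monte_carlo_errors(
            fit,
            obj,
            n_sims=config.n_sims,
            seed=seed,
            rules=config.elimination,
            max_iter=config.max_iter,
        )
        return unit, name, errors, removed, None
    except ErrorEstimationFailure as exc:
        return unit, name, {}, config.n_sims, str(exc)


def run_protocol(dataset: DispersionDataset, config: ProtocolConfig) -> ProtocolReport:
    """Run the full automated protocol on one dataset."""
    t_start = time.time()
    report = ProtocolReport(config_snapshot=_snapshot(config))
    report.log_lines.append(
        f"protocol start: {len(dataset.spins)} spins, {dataset.n_values()} values, "
        f"seed={config.seed}, workers={config.workers}"
    )

    # stage 1+2: non-clustered pass with elimination
    spin_ids = sorted(s.spin_id for s in dataset.spins)
    unit_args = [(dataset, config, sid) for sid in spin_ids]
    spin_results: dict[str, dict[str, FitResult]] = {}
    for unit, fits, skipped, log in parallel_map(_fit_unit, unit_args, config.workers):
        sid = unit.split(":", 1)[1]
        spin_results[sid] = fits
        for name, fit in fits.items():
            report.fits[(unit, name)] = fit
        for name, reason in skipped.items():
            report.skipped[(unit, name)] = reason
        report.log_lines.extend(log)

    # stage 3: clustered pass
    clusters = dict(config.clusters)
    for cid, members in dataset.clusters().items():
        clusters.setdefault(cid, members)
    clusters = {
        cid: sorted(members)
        for cid, members in clusters.items()
        if len(members) >= 2
    }
    cluster_args = [
        (dataset, config, cid, members, {sid: spin_results[sid] for sid in members})
        for cid, members in sorted(clusters.items())
    ]
    for unit, fits, skipped, log in parallel_map(
        _fit_cluster_unit, cluster_args, config.workers
    ):
        for name, fit in fits.items():
            report.fits[(unit, name)] = fit
        for name, reason in skipped.items():
            report.skipped[(unit, name)] = reason
        report.log_lines.extend(log)

    # final units for selection: clusters plus unclustered spins
    clustered_spins = {sid for members in clusters.values() for sid in members}
    units: dict[str, list[str]] = {
        f"cluster:{cid}": members for cid, members in sorted(clusters.items())
    }
    for sid in spin_ids:
        if sid not in clustered_spins:
            units[f"spin:{sid}"] = [sid]
    for unit, members in units.items():
        for sid in members:
            report.spin_unit[sid] = unit

    # stage 4: Monte Carlo errors for the surviving final fits
    if config.mc_enabled:
        mc_jobs = []
        idx = 0
        for unit in sorted(units):
            for name in config.models:
                fit = report.fits.get((unit, name))
                seed = (config.seed * 100003 + idx) % (2**31)
                idx += 1
                if fit is None or fit.eliminated:
                    continue
                mc_jobs.append((dataset, config, unit, name, fit, seed))
        for unit, name, errors, removed, failure in parallel_map(
            _mc_unit, mc_jobs, config.workers
        ):
            fit = report.fits[(unit, name)]
            fit.mc_errors = errors
            fit.mc_sims_removed = removed
            if failure:
                fit.eliminated = True
                fit.elimination_reason = failure
                report.log_lines.append(f"{unit} {name}: MC failure: {failure}")
            elif removed:
                report.log_lines.append(
                    f"{unit} {name}: {removed}/{config.n_sims} MC sims eliminated"
                )

    # stage 5: final AIC selection over the stored fits
    for unit in sorted(units):
        results = {
            name: report.fits[(unit, name)]
            for name in config.models
            if (unit, name) in report.fits
        }
        if not results:
            report.log_lines.append(f"{unit}: no fit results; selection skipped")
            continue
        outcome = select_model(results)
        report.outcomes[unit] = outcome
        report.log_lines.append(
            f"{unit}: chosen={outcome.chosen} "
            f"ranking={[(m, round(a, 3)) for m, a in outcome.ranked]}"
        )

    _build_curves(dataset, report)
    report.log_lines.append(f"protocol done in {time.time() - t_start:.2f} s")
    return report


def _build_curves(dataset: DispersionDataset, report: ProtocolReport) -> None:
    for sid, unit in sorted(report.spin_unit.items()):
        if unit not in report.outcomes:
            continue
        chosen = report.outcomes[unit].chosen
        fit = report.fits.get((unit, chosen))
        if fit is None:
            continue
        obj = Objective(chosen, dataset, list(fit.spin_ids))
        calc = obj.back_calc(fit.params.values)[sid]
        rows = []
        for j, (idx, pt, rv) in enumerate(dataset.iter_spin_values(sid)):
            rows.append(
                {
                    "x": pt.nu_cpmg if pt.is_cpmg else pt.omega1,
                    "nu_cpmg": pt.nu_cpmg,
                    "omega1": pt.omega1,
                    "offset_ppm": pt.offset,
                    "field_h1_mhz": pt.field_h1_mhz,
                    "exp_type": pt.exp_type,
                    "observed": rv.value,
                    "error": rv.error,
                    "calculated": float(calc[j]),
                    "model": chosen,
                }
            )
        report.curves[sid] = rows


def _snapshot(config: ProtocolConfig) -> dict:
    from . import __version__

    return {
        "version": __version__,
        "seed": config.seed,
        "models": list(config.models),
        "clusters": {k: list(v) for k, v in config.clusters.items()},
        "grid_points": config.grid_points,
        "fatol": config.fatol,
        "xatol": config.xatol,
        "max_iter": config.max_iter,
        "n_sims": config.n_sims,
        "workers": config.workers,
    }
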