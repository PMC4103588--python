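"""Validation studies: the package exercising itself end to end.

These functions define the package's standing validation suite — the
analytic-versus-numeric cross-checks, parameter-recovery and
model-selection simulations, warm-start soundness comparisons and Monte
Carlo calibration — with their study designs fixed in one place so the
test suite and the reproduction script run the same computations.
"""

from __future__ import annotations

import math

import numpy as np

from .data import DispersionDataset, ExperimentPoint, RateValue, SpinSystem
from .fitting import Objective, ParamKey, grid_search, minimise
from .models import cpmg, numeric, r1rho
from .pipeline import ProtocolConfig, run_protocol
from .selection import eliminate, monte_carlo_errors, select_model
from .simulate import SimDesign, default_cpmg_design, simulate_dataset
from .units import ppm_to_rad_per_s

__all__ = [
    "crossval_cpmg",
    "crossval_r1rho",
    "recovery_study",
    "selection_study",
    "warmstart_study",
    "mc_calibration",
]

# the fixed cross-validation sweep: populations, rates, shifts, fields
SWEEP_PA = (0.9, 0.95, 0.99)
SWEEP_KEX = (500.0, 2000.0, 1e4)
SWEEP_DW_PPM = (1.0, 3.0)
SWEEP_FIELDS = (600.0, 800.0)
SWEEP_T = 0.04
SWEEP_NU = tuple(12.5 * m for m in range(4, 84, 4))  # 50 .. 1000 Hz


def crossval_cpmg() -> dict[str, float]:
    """Worst relative deviation of each analytic CPMG model from the
    numeric reference, inside each model's validity regime.

    Regimes: CR72 for kex >= 2*dw (it degrades towards slow exchange);
    LM63 for kex >= 20*dw (fast exchange); IT99 for skewed populations
    (pA >= 0.95) outside the intermediate window (kex/dw outside
    [0.5, 3]); the very-slow-exchange model is checked on its own regime
    (pA = 0.99, kex <= 200 1/s) since the main sweep contains no
    sufficiently slow points.  The MMQ extension is checked against the
    multiple-quantum propagation on a representative skewed sweep.
    """
    nus = np.array(SWEEP_NU)
    worst = {"CR72": 0.0, "LM63": 0.0, "IT99": 0.0}
    r20 = 10.0
    for pA in SWEEP_PA:
        for kex in SWEEP_KEX:
            for dw_ppm in SWEEP_DW_PPM:
                for field in SWEEP_FIELDS:
                    dw = ppm_to_rad_per_s(dw_ppm, field, "15N")
                    ns = np.array(
                        [
                            numeric.ns_cpmg_2site(r20, r20, pA, kex, dw, nu, SWEEP_T)
                            for nu in nus
                        ]
                    )
                    if kex >= 2.0 * dw:
                        an = cpmg.r2eff_cr72(r20, r20, pA, kex, dw, nus)
                        worst["CR72"] = max(worst["CR72"], _maxrel(an, ns))
                    if kex >= 20.0 * dw:
                        an = cpmg.r2eff_lm63(r20, pA * (1 - pA) * dw**2, kex, nus)
                        worst["LM63"] = max(worst["LM63"], _maxrel(an, ns))
                    ratio = kex / dw
                    if pA >= 0.95 and (ratio >= 3.0 or ratio <= 0.5):
                        an = cpmg.r2eff_it99(r20, pA, kex, dw, nus)
                        worst["IT99"] = max(worst["IT99"], _maxrel(an, ns))
    # very slow exchange for the forward-rate model
    worst["TSMFK01"] = 0.0
    dw = ppm_to_rad_per_s(4.0, 600.0, "15N")
    for kex in (50.0, 100.0, 200.0):
        pA = 0.99
        an = cpmg.r2eff_tsmfk01(r20, (1 - pA) * kex, dw, nus)
        ns = np.array(
            [numeric.ns_cpmg_2site(r20, r20, pA, kex, dw, nu, SWEEP_T) for nu in nus]
        )
        worst["TSMFK01"] = max(worst["TSMFK01"], _maxrel(an, ns))
    # multiple-quantum extension on a skewed sweep
    worst["MMQ_CR72"] = 0.0
    for pA, kex, dwp, dwhp in [
        (0.95, 2000.0, 2.0, 0.5),
        (0.9, 1e4, 3.0, 1.0),
        (0.99, 2000.0, 3.0, 1.0),
    ]:
        dw = ppm_to_rad_per_s(dwp, 600.0, "15N")
        dwh = ppm_to_rad_per_s(dwhp, 600.0, "1H")
        an = cpmg.r2eff_mmq_cr72(r20, r20, pA, kex, dw, dwh, nus, "CPMG_MQ")
        ns = np.array(
            [
                numeric.ns_mmq_2site(r20, r20, pA, kex, dw, dwh, nu, SWEEP_T, "CPMG_MQ")
                for nu in nus
            ]
        )
        worst["MMQ_CR72"] = max(worst["MMQ_CR72"], _maxrel(an, ns))
    return worst


def crossval_r1rho() -> dict[str, float]:
    """Worst relative deviation of the rotating-frame models from the
    numeric reference: the fast-exchange model for kex >= 10*dw, the
    skewed-population models for pB <= 0.05."""
    r1, r2, T = 1.5, 10.0, 0.1
    worst = {"DPL94": 0.0, "TP02": 0.0, "MP05": 0.0}
    for pA in SWEEP_PA:
        for kex in SWEEP_KEX:
            for dw_ppm in SWEEP_DW_PPM:
                for field in SWEEP_FIELDS:
                    dw = ppm_to_rad_per_s(dw_ppm, field, "15N")
                    for om1_hz in (400.0, 1000.0, 2000.0):
                        for off_hz in (-300.0, 0.0, 500.0):
                            om1 = 2 * math.pi * om1_hz
                            oa = 2 * math.pi * off_hz
                            geom = r1rho.spin_lock_geometry(om1, oa, dw, pA)
                            ns = None
                            if kex >= 10.0 * dw:
                                ns = numeric.ns_r1rho_2site(
                                    r1, r2, r2, pA, kex, dw, oa, om1, T
                                )
                                an = r1rho.r1rho_dpl94(
                                    r1, r2, pA * (1 - pA) * dw * dw, kex, geom
                                )
                                worst["DPL94"] = max(
                                    worst["DPL94"], abs(an - ns) / ns
                                )
                            if pA >= 0.95:
                                if ns is None:
                                    ns = numeric.ns_r1rho_2site(
                                        r1, r2, r2, pA, kex, dw, oa, om1, T
                                    )
                                tp = r1rho.r1rho_tp02(r1, r2, pA, kex, dw, geom)
                                mp = r1rho.r1rho_mp05(r1, r2, pA, kex, dw, geom)
                                worst["TP02"] = max(worst["TP02"], abs(tp - ns) / ns)
                                worst["MP05"] = max(worst["MP05"], abs(mp - ns) / ns)
    return worst


def _maxrel(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.max(np.abs(a - b) / np.abs(b)))


TRUE_PA, TRUE_KEX, TRUE_DW = 0.95, 2000.0, 2.0


def recovery_study(
    n_datasets: int = 100, n_sims: int = 50, seed: int = 0
) -> dict[str, float]:
    """Parameter recovery over synthetic two-field CPMG studies.

    Each replicate simulates a 2-field x 15-frequency dispersion with
    0.5 1/s rate noise, fits the general two-site closed form, and runs
    Monte Carlo error propagation.  Reports median relative errors and
    the fraction of replicates whose truth lies within 3 Monte Carlo
    standard deviations for every kinetic parameter.
    """
    rel_err: dict[str, list[float]] = {"pA": [], "kex": [], "dw": []}
    covered = 0
    truth = {"pA": TRUE_PA, "kex": TRUE_KEX, "dw:R2:N": TRUE_DW}
    for i in range(n_datasets):
        ds = simulate_dataset(default_cpmg_design(seed=seed * 1009 + i))
        obj = Objective("CR72", ds)
        fit = minimise(obj, grid_search(obj))
        errors, _ = monte_carlo_errors(
            fit, obj, n_sims=n_sims, seed=(seed * 131 + i) % 2**31
        )
        est = fit.params.as_dict()
        rel_err["pA"].append(abs(est["pA"] - TRUE_PA) / TRUE_PA)
        rel_err["kex"].append(abs(est["kex"] - TRUE_KEX) / TRUE_KEX)
        rel_err["dw"].append(abs(est["dw:R2:N"] - TRUE_DW) / TRUE_DW)
        if all(
            abs(est[name] - val) <= 3.0 * errors[name] for name, val in truth.items()
        ):
            covered += 1
    return {
        "median_rel_err_pA": float(np.median(rel_err["pA"])),
        "median_rel_err_kex": float(np.median(rel_err["kex"])),
        "median_rel_err_dw": float(np.median(rel_err["dw"])),
        "coverage_3sd": covered / n_datasets,
    }


def selection_study(
    n_datasets: int = 100, seed: int = 0, exchange: bool = False
) -> float:
    """Fraction of replicates on which AIC selection behaves correctly.

    With ``exchange=False`` the data are flat (no exchange) and the
    correct choice is the no-exchange model; with ``exchange=True`` the
    data carry a strong dispersion (Rex about 15 1/s) and the correct
    choice is any exchange model.  Candidates: NoRex, LM63, CR72.
    """
    n_correct = 0
    for i in range(n_datasets):
        s = (seed * 2003 + i) % 2**31
        if exchange:
            ds = simulate_dataset(default_cpmg_design(seed=s))
        else:
            d = default_cpmg_design(seed=s, model="NoRex")
            d.true_params = {"R2:N": {"r20": {600.0: 10.0, 800.0: 10.0}}}
            ds = simulate_dataset(d)
        fits = {}
        for name in ("NoRex", "LM63", "CR72"):
            obj = Objective(name, ds)
            fit = minimise(obj, grid_search(obj))
            fit.eliminated, fit.elimination_reason = eliminate(fit)
            fits[name] = fit
        chosen = select_model(fits).chosen
        if (chosen != "NoRex") == exchange:
            n_correct += 1
    return n_correct / n_datasets


def _mmq_fixture(seed: int) -> DispersionDataset:
    spins = [SpinSystem("R2:N")]
    points = []
    for et in ("CPMG_SQ", "CPMG_ZQ", "CPMG_DQ", "CPMG_MQ"):
        for m in range(4, 44, 4):
            points.append(
                ExperimentPoint(et, 600.0, nu_cpmg=12.5 * m, relax_time_T=0.04)
            )
    spin = spins[0]
    from .catalog import back_calc_spin

    params = {"r20": {600.0: 10.0}, "pA": 0.95, "kex": 2000.0, "dw": 2.0, "dwH": 0.3}
    rates = back_calc_spin("NS_MMQ_2site", spin, params, points)
    rng = np.random.default_rng(seed)
    values = {
        ("R2:N", i): RateValue(float(r + rng.normal(0, 0.5)), 0.5)
        for i, r in enumerate(rates)
    }
    return DispersionDataset(spins, points, values)


def warmstart_study(seed: int = 0) -> dict[str, float]:
    """Warm-start soundness: protocol chi2 over exhaustive-route chi2.

    Three fixtures exercise the three grid-skipping devices: a two-spin
    clustered CPMG study (nesting + cluster averaging), an MMQ study
    (equivalence seeding of the numeric models), and an off-resonance
    R1rho study (the phi_ex -> dw translation chain).  For every
    (work unit, model) pair the protocol-route chi2 is divided by the
    chi2 of an independent exhaustive grid-plus-simplex fit; the maximum
    ratio is returned per fixture.
    """
    out: dict[str, float] = {}

    # CPMG fixture with a cluster
    design = default_cpmg_design(seed=seed * 7919 + 5, n_spins=2)
    design.cluster_ids = {"R2:N": "c1", "R3:N": "c1"}
    ds = simulate_dataset(design)
    cfg = ProtocolConfig(
        seed=seed + 1,
        models=["NoRex", "LM63", "IT99", "TSMFK01", "CR72", "NS_CPMG_2site"],
        mc_enabled=False,
    )
    out["cpmg_cluster"] = _route_ratio(ds, cfg, ns_grid_points=7)

    # MMQ fixture
    ds = _mmq_fixture(seed * 523 + 11)
    cfg = ProtocolConfig(
        seed=seed + 2, models=["NoRex", "MMQ_CR72", "NS_MMQ_2site"], mc_enabled=False
    )
    out["mmq"] = _route_ratio(ds, cfg, ns_grid_points=5)

    # R1rho fixture
    r_design = SimDesign(
        model="TP02",
        true_params={
            "R5:N": {"r20": {600.0: 10.0}, "pA": 0.95, "kex": 2000.0, "dw": 2.0}
        },
        fields_mhz=[600.0],
        seed=seed * 271 + 17,
        omega1=[400.0, 700.0, 1000.0, 1500.0, 2200.0],
        offsets_ppm=[-2.0, 0.0, 2.0],
        r1=1.5,
        sigma=0.2,
    )
    ds = simulate_dataset(r_design)
    cfg = ProtocolConfig(
        seed=seed + 3,
        models=["NoRex", "M61", "DPL94", "TP02", "MP05", "NS_R1rho_2site"],
        mc_enabled=False,
    )
    out["r1rho"] = _route_ratio(ds, cfg, ns_grid_points=7)
    return out


def _route_ratio(ds: DispersionDataset, cfg: ProtocolConfig, ns_grid_points: int) -> float:
    report = run_protocol(ds, cfg)
    worst = 0.0
    for (unit, name), fit in report.fits.items():
        spin_ids = list(fit.spin_ids)
        obj = Objective(name, ds, spin_ids)
        gp = ns_grid_points if name.startswith("NS_") else cfg.grid_points
        exhaustive = minimise(obj, grid_search(obj, gp))
        if exhaustive.chi2 <= 0:
            continue
        worst = max(worst, fit.chi2 / exhaustive.chi2)
    return worst


def mc_calibration(seed: int = 0, n_sims: int = 500) -> dict[str, float]:
    """Monte Carlo errors against the closed-form standard error.

    A flat single-field dispersion has one free parameter — the decay
    rate — whose weighted least-squares standard error is sigma/sqrt(N).
    The Monte Carlo estimate should reproduce it.
    """
    sigma = 0.5
    d = default_cpmg_design(seed=seed * 401 + 3, model="NoRex", fields=(600.0,), sigma=sigma)
    d.true_params = {"R2:N": {"r20": {600.0: 10.0}}}
    ds = simulate_dataset(d)
    obj = Objective("NoRex", ds)
    fit = minimise(obj, grid_search(obj))
    errors, removed = monte_carlo_errors(
        fit, obj, n_sims=n_sims, seed=(seed * 17 + 5) % 2**31
    )
    mc_sd = list(errors.values())[0]
    closed_form = sigma / math.sqrt(obj.n)
    return {
        "mc_sd": mc_sd,
        "closed_form_se": closed_form,
        "ratio": mc_sd / closed_form,
        "removed": removed,
    }
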