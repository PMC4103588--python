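"""The dispersion-model catalogue and parameter templates.

Each model is described by a ``ModelSpec``: an ordered set of parameters,
each with a scope (cluster-global, per-spin, or per-spin-per-field), box
bounds, and a grid-search rule.  The catalogue order runs from simple to
complex so that every warm-start source is fitted before the model that
needs it.

Fitted-parameter units are user-facing: shift differences dw/dwH in ppm,
phi_ex in ppm^2 (converted to rad^2/s^2 at each point's field, so one
value describes data at several static fields), rates in 1/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CPMG_TYPES, DispersionDataset, ExperimentPoint, SpinSystem
from .models import cpmg, numeric, r1rho
from .units import offset_ppm_to_rad_per_s, ppm_to_rad_per_s

__all__ = [
    "ParamDef",
    "ModelSpec",
    "MODEL_CATALOG",
    "list_models",
    "get_model",
    "back_calc_spin",
    "SCOPE_GLOBAL",
    "SCOPE_SPIN",
    "SCOPE_SPIN_FIELD",
]

log = logging.getLogger(__name__)

SCOPE_GLOBAL = "cluster-global"
SCOPE_SPIN = "per-spin"
SCOPE_SPIN_FIELD = "per-spin-per-field"


@dataclass(frozen=True)
class ParamDef:
    """One model parameter: symbol, sharing scope, bounds and grid rule.

    ``grid`` is "lin" or "log" for gridded parameters (11 points by
    default) or "seed" for parameters initialised from the data (baseline
    rates take the observed rate at the largest nu_cpmg or omega1).
    ``grid_lower`` overrides the lower bound for log grids whose physical
    lower bound is zero.
    """

    symbol: str
    scope: str
    lower: float
    upper: float
    grid: str = "lin"
    grid_lower: float | None = None


# default box bounds; physically wide, exposed here in one place
_R20 = dict(lower=0.1, upper=200.0, grid="seed")
_PA = dict(lower=0.5, upper=1.0 - 1e-6, grid="lin")
_KEX = dict(lower=1.0, upper=1e6, grid="log")
_DW = dict(lower=0.0, upper=30.0, grid="lin")
_PHI = dict(lower=0.0, upper=70.0, grid="log", grid_lower=1e-2)  # ppm^2
_KAB = dict(lower=1e-2, upper=1e4, grid="log")


@dataclass(frozen=True)
class ModelSpec:
    """A dispersion model: name, data kind and parameter template."""

    name: str
    kind: str  # "any", "cpmg_sq", "cpmg_mmq", "r1rho"
    params: tuple[ParamDef, ...]

    def param(self, symbol: str) -> ParamDef:
        for p in self.params:
            if p.symbol == symbol:
                return p
        raise KeyError(symbol)

    def k(self, n_spins: int, n_fields_per_spin: dict[str, int] | int) -> int:
        """Free-parameter count for a cluster."""
        if isinstance(n_fields_per_spin, int):
            n_fields_per_spin = {str(i): n_fields_per_spin for i in range(n_spins)}
        k = 0
        for p in self.params:
            if p.scope == SCOPE_GLOBAL:
                k += 1
            elif p.scope == SCOPE_SPIN:
                k += n_spins
            else:
                k += sum(n_fields_per_spin.values())
        return k

    def supports(self, exp_type: str) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "cpmg_sq":
            return exp_type == "CPMG_SQ"
        if self.kind == "cpmg_mmq":
            return exp_type in CPMG_TYPES
        if self.kind == "r1rho":
            return exp_type == "R1RHO"
        raise ValueError(self.kind)


def _p(symbol: str, scope: str, **kw) -> ParamDef:
    return ParamDef(symbol=symbol, scope=scope, **kw)


MODEL_CATALOG: tuple[ModelSpec, ...] = (
    ModelSpec("NoRex", "any", (_p("r20", SCOPE_SPIN_FIELD, **_R20),)),
    ModelSpec(
        "LM63",
        "cpmg_sq",
        (
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("phi_ex", SCOPE_SPIN, **_PHI),
        ),
    ),
    ModelSpec(
        "IT99",
        "cpmg_sq",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "TSMFK01",
        "cpmg_sq",
        (
            _p("k_ab", SCOPE_GLOBAL, **_KAB),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "CR72",
        "cpmg_sq",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "MMQ_CR72",
        "cpmg_mmq",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
            _p("dwH", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "NS_CPMG_2site",
        "cpmg_sq",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "NS_MMQ_2site",
        "cpmg_mmq",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
            _p("dwH", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "M61",
        "r1rho",
        (
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("phi_ex", SCOPE_SPIN, **_PHI),
        ),
    ),
    ModelSpec(
        "DPL94",
        "r1rho",
        (
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("phi_ex", SCOPE_SPIN, **_PHI),
        ),
    ),
    ModelSpec(
        "TP02",
        "r1rho",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "MP05",
        "r1rho",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
    ModelSpec(
        "NS_R1rho_2site",
        "r1rho",
        (
            _p("pA", SCOPE_GLOBAL, **_PA),
            _p("kex", SCOPE_GLOBAL, **_KEX),
            _p("r20", SCOPE_SPIN_FIELD, **_R20),
            _p("dw", SCOPE_SPIN, **_DW),
        ),
    ),
)

_BY_NAME = {m.name: m for m in MODEL_CATALOG}

CATALOG_ORDER = {m.name: i for i, m in enumerate(MODEL_CATALOG)}


def list_models() -> tuple[ModelSpec, ...]:
    """The full catalogue, in optimization (simple-to-complex) order."""
    return MODEL_CATALOG


def get_model(name: str) -> ModelSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; catalogue: {[m.name for m in MODEL_CATALOG]}"
        ) from None


# ---------------------------------------------------------------------------
# back-calculation dispatch


def _phi_rad(phi_ppm2: float, field: float, isotope: str) -> float:
    scale = ppm_to_rad_per_s(1.0, field, isotope)
    return phi_ppm2 * scale * scale


def back_calc_spin(
    model: ModelSpec | str,
    spin: SpinSystem,
    params: dict,
    points: list[ExperimentPoint],
) -> np.ndarray:
    """Back-calculate rates for one spin at the given conditions.

    ``params`` holds the fitted values in user-facing units: ``r20`` is a
    map field -> baseline rate (interpreted as R1rho' for R1RHO points),
    ``dw``/``dwH`` in ppm, ``phi_ex`` in ppm^2, ``pA``/``kex``/``k_ab``
    as usual.  Returns one rate per point, in point order.
    """
    if isinstance(model, str):
        model = get_model(model)
    name = model.name
    out = np.empty(len(points))
    r20_map = params.get("r20", {})

    # group CPMG points by (field, exp_type) for vectorised kernels
    if name in ("NoRex",):
        for i, pt in enumerate(points):
            r20 = r20_map[pt.field_h1_mhz]
            if pt.is_cpmg:
                out[i] = r20
            else:
                geom = _geometry(pt, spin, params.get("dw", 0.0), params.get("pA", 1.0))
                out[i] = r1rho.r1rho_norex(_r1(pt), r20, geom)
        return out

    if name in ("LM63", "CR72", "IT99", "TSMFK01", "MMQ_CR72"):
        groups: dict[tuple[float, str], list[int]] = {}
        for i, pt in enumerate(points):
            if not pt.is_cpmg:
                raise ValueError(f"{name} cannot describe {pt.exp_type} data")
            groups.setdefault((pt.field_h1_mhz, pt.exp_type), []).append(i)
        for (field, exp_type), idx in groups.items():
            nu = np.array([points[i].nu_cpmg for i in idx])
            r20 = r20_map[field]
            if name == "LM63":
                rates = cpmg.r2eff_lm63(
                    r20, _phi_rad(params["phi_ex"], field, spin.isotope), params["kex"], nu
                )
            elif name == "CR72":
                dw = ppm_to_rad_per_s(params["dw"], field, spin.isotope)
                rates = cpmg.r2eff_cr72(r20, r20, params["pA"], params["kex"], dw, nu)
            elif name == "IT99":
                dw = ppm_to_rad_per_s(params["dw"], field, spin.isotope)
                rates = cpmg.r2eff_it99(r20, params["pA"], params["kex"], dw, nu)
            elif name == "TSMFK01":
                dw = ppm_to_rad_per_s(params["dw"], field, spin.isotope)
                rates = cpmg.r2eff_tsmfk01(r20, params["k_ab"], dw, nu)
            else:  # MMQ_CR72
                dw = ppm_to_rad_per_s(params["dw"], field, spin.isotope)
                dwh = ppm_to_rad_per_s(params.get("dwH", 0.0), field, "1H")
                rates = cpmg.r2eff_mmq_cr72(
                    r20, r20, params["pA"], params["kex"], dw, dwh, nu, exp_type
                )
            out[np.array(idx)] = rates
        return out

    if name in ("NS_CPMG_2site", "NS_MMQ_2site"):
        for i, pt in enumerate(points):
            if not pt.is_cpmg:
                raise ValueError(f"{name} cannot describe {pt.exp_type} data")
            r20 = r20_map[pt.field_h1_mhz]
            dw = ppm_to_rad_per_s(params["dw"], pt.field_h1_mhz, spin.isotope)
            if name == "NS_CPMG_2site":
                out[i] = numeric.ns_cpmg_2site(
                    r20, r20, params["pA"], params["kex"], dw, pt.nu_cpmg, pt.relax_time_T
                )
            else:
                dwh = ppm_to_rad_per_s(params.get("dwH", 0.0), pt.field_h1_mhz, "1H")
                out[i] = numeric.ns_mmq_2site(
                    r20,
                    r20,
                    params["pA"],
                    params["kex"],
                    dw,
                    dwh,
                    pt.nu_cpmg,
                    pt.relax_time_T,
                    pt.exp_type,
                )
        return out

    if name in ("M61", "DPL94", "TP02", "MP05", "NS_R1rho_2site"):
        for i, pt in enumerate(points):
            if pt.exp_type != "R1RHO":
                raise ValueError(f"{name} cannot describe {pt.exp_type} data")
            r20 = r20_map[pt.field_h1_mhz]
            if name in ("M61", "DPL94"):
                geom = _geometry(pt, spin, 0.0, 1.0)
                phi = _phi_rad(params["phi_ex"], pt.field_h1_mhz, spin.isotope)
                if name == "M61":
                    if abs(geom.omega_avg) > 0.01 * geom.omega1:
                        log.warning(
                            "M61 assumes on-resonance data; |offset|/omega1 = %.3g "
                            "for spin %s",
                            abs(geom.omega_avg) / geom.omega1,
                            spin.spin_id,
                        )
                    out[i] = r1rho.r1rho_m61(r20, phi, params["kex"], geom)
                else:
                    out[i] = r1rho.r1rho_dpl94(_r1(pt), r20, phi, params["kex"], geom)
            else:
                dw = ppm_to_rad_per_s(params["dw"], pt.field_h1_mhz, spin.isotope)
                geom = _geometry(pt, spin, dw, params["pA"])
                if name == "TP02":
                    out[i] = r1rho.r1rho_tp02(
                        _r1(pt), r20, params["pA"], params["kex"], dw, geom
                    )
                elif name == "MP05":
                    out[i] = r1rho.r1rho_mp05(
                        _r1(pt), r20, params["pA"], params["kex"], dw, geom
                    )
                else:
                    T = pt.relax_time_T if pt.relax_time_T is not None else 0.1
                    out[i] = numeric.ns_r1rho_2site(
                        _r1(pt),
                        r20,
                        r20,
                        params["pA"],
                        params["kex"],
                        dw,
                        geom.omega_a,
                        geom.omega1,
                        T,
                    )
        return out

    raise KeyError(f"unknown model {name!r}")


def _r1(pt: ExperimentPoint) -> float:
    if pt.r1 is None:
        raise ValueError("off-resonance R1rho models need a measured R1")
    return pt.r1


def _geometry(pt: ExperimentPoint, spin: SpinSystem, dw_rad: float, pA: float):
    omega1 = 2.0 * np.pi * pt.omega1
    offset = pt.offset if pt.offset is not None else 0.0
    omega_a = offset_ppm_to_rad_per_s(offset, pt.field_h1_mhz, spin.isotope)
    return r1rho.spin_lock_geometry(omega1, omega_a, dw_rad, pA)
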