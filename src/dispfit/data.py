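"""Domain types for relaxation-dispersion datasets.

A dataset couples three things: the exchanging sites (spins), the
measurement conditions (static field plus either a CPMG pulse-train
frequency or a spin-lock amplitude/offset), and the observed effective
relaxation rates R2eff or R1rho with one-standard-deviation errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import math

from .units import GYROMAGNETIC_RATIO

__all__ = [
    "EXP_TYPES",
    "CPMG_TYPES",
    "SpinSystem",
    "ExperimentPoint",
    "RateValue",
    "DispersionDataset",
    "DatasetError",
]

#: Supported experiment types.  CPMG types are distinguished by coherence
#: (single, zero, double, multiple quantum); R1RHO is off/on-resonance
#: rotating-frame relaxation.
CPMG_TYPES = ("CPMG_SQ", "CPMG_MQ", "CPMG_ZQ", "CPMG_DQ")
EXP_TYPES = CPMG_TYPES + ("R1RHO",)


class DatasetError(ValueError):
    """Raised when dataset construction violates an invariant."""


@dataclass(frozen=True)
class SpinSystem:
    """One exchanging site (residue/atom) and its cluster membership.

    Spins in the same cluster are constrained to share the global kinetic
    and thermodynamic parameters (pA, kex) during a clustered fit while
    keeping per-spin shift differences and baseline rates.
    """

    spin_id: str
    isotope: str = "15N"
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not self.spin_id:
            raise DatasetError("spin_id must be a non-empty string")
        if self.isotope not in GYROMAGNETIC_RATIO:
            raise DatasetError(
                f"isotope {self.isotope!r} has no gyromagnetic-ratio entry"
            )


@dataclass(frozen=True)
class ExperimentPoint:
    """One measurement condition.

    For CPMG experiments ``nu_cpmg`` (Hz) and the constant relaxation period
    ``relax_time_T`` (s) are required; for R1rho experiments the spin-lock
    amplitude ``omega1`` (Hz, i.e. omega1/2pi), the offset of the state-A
    resonance from the spin-lock carrier (ppm) and, for off-resonance
    models, the measured longitudinal rate ``r1`` (1/s) are used.
    """

    exp_type: str
    field_h1_mhz: float
    nu_cpmg: float | None = None
    relax_time_T: float | None = None
    omega1: float | None = None
    offset: float | None = None
    r1: float | None = None

    def __post_init__(self) -> None:
        if self.exp_type not in EXP_TYPES:
            raise DatasetError(f"unknown exp_type {self.exp_type!r}")
        if not (self.field_h1_mhz > 0):
            raise DatasetError("field_h1_mhz must be positive")
        if self.exp_type in CPMG_TYPES:
            if self.nu_cpmg is None or not (self.nu_cpmg > 0):
                raise DatasetError("CPMG points require nu_cpmg > 0")
            if self.relax_time_T is None or not (self.relax_time_T > 0):
                raise DatasetError("CPMG points require relax_time_T > 0")
            if self.omega1 is not None or self.offset is not None:
                raise DatasetError("CPMG points must not carry spin-lock fields")
        else:  # R1RHO
            if self.omega1 is None or not (self.omega1 > 0):
                raise DatasetError("R1rho points require omega1 > 0")
            if self.nu_cpmg is not None:
                raise DatasetError("R1rho points must not carry nu_cpmg")
            if self.relax_time_T is not None and not (self.relax_time_T > 0):
                raise DatasetError("relax_time_T must be positive when given")

    @property
    def is_cpmg(self) -> bool:
        return self.exp_type in CPMG_TYPES


@dataclass(frozen=True)
class RateValue:
    """An observed rate (R2eff or R1rho, 1/s) with its one-sigma error."""

    value: float
    error: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise DatasetError("rate value must be finite")
        if not (self.error >= 0):
            raise DatasetError("rate error must be >= 0")


@dataclass
class DispersionDataset:
    """All observed rates, indexed by (spin_id, point index).

    Invariants enforced at construction: every value key refers to an
    existing spin and point, every spin has at least one value, spin ids
    are unique, and all CPMG points observed for one (spin, field) share a
    single constant relaxation period.
    """

    spins: list[SpinSystem]
    points: list[ExperimentPoint]
    values: dict[tuple[str, int], RateValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.spin_id for s in self.spins]
        if len(set(ids)) != len(ids):
            raise DatasetError("spin_id values must be unique within a dataset")
        known = set(ids)
        for (sid, idx) in self.values:
            if sid not in known:
                raise DatasetError(f"value references unknown spin {sid!r}")
            if not (0 <= idx < len(self.points)):
                raise DatasetError(f"value references unknown point index {idx}")
        covered = {sid for (sid, _) in self.values}
        missing = known - covered
        if missing:
            raise DatasetError(f"spins without any value: {sorted(missing)}")
        # one constant relaxation period per (spin, field) for CPMG data
        for sid in known:
            periods: dict[float, float] = {}
            for idx in self.point_indices(sid):
                pt = self.points[idx]
                if not pt.is_cpmg:
                    continue
                prev = periods.setdefault(pt.field_h1_mhz, pt.relax_time_T)
                if prev != pt.relax_time_T:
                    raise DatasetError(
                        f"spin {sid!r} at {pt.field_h1_mhz} MHz mixes relaxation "
                        f"periods {prev} and {pt.relax_time_T}"
                    )

    # -- access helpers -------------------------------------------------

    def spin(self, spin_id: str) -> SpinSystem:
        for s in self.spins:
            if s.spin_id == spin_id:
                return s
        raise KeyError(spin_id)

    def point_indices(self, spin_id: str) -> list[int]:
        """Indices of the points observed for one spin, in point order."""
        return sorted(idx for (sid, idx) in self.values if sid == spin_id)

    def fields(self, spin_id: str | None = None) -> list[float]:
        """Sorted distinct static fields, optionally restricted to one spin."""
        if spin_id is None:
            return sorted({p.field_h1_mhz for p in self.points})
        return sorted(
            {self.points[i].field_h1_mhz for i in self.point_indices(spin_id)}
        )

    def exp_types(self) -> set[str]:
        return {p.exp_type for p in self.points}

    def iter_spin_values(self, spin_id: str) -> Iterator[tuple[int, ExperimentPoint, RateValue]]:
        for idx in self.point_indices(spin_id):
            yield idx, self.points[idx], self.values[(spin_id, idx)]

    def n_values(self) -> int:
        return len(self.values)

    def clusters(self) -> dict[str, list[str]]:
        """Cluster membership: cluster_id -> sorted spin ids (>= 2 members)."""
        out: dict[str, list[str]] = {}
        for s in self.spins:
            if s.cluster_id is not None:
                out.setdefault(s.cluster_id, []).append(s.spin_id)
        return {cid: sorted(m) for cid, m in out.items()}

    def with_values(self, values: dict[tuple[str, int], RateValue]) -> "DispersionDataset":
        """A copy of this dataset with the observed rates replaced."""
        return DispersionDataset(list(self.spins), list(self.points), dict(values))
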