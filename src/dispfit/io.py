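"""Readers and writers for peak lists and dispersion tables.

Two external formats are supported:

* Sparky ``.list`` peak lists (whitespace-delimited, one peak per row,
  header tolerated) — intensities only;
* a generic CSV dispersion table with one row per (spin, condition):
  columns ``spin_id, exp_type, field_h1_mhz, nu_cpmg, relax_time_T,
  omega1, offset_ppm, r1, r2eff, r2eff_err`` (header mandatory; cells for
  inapplicable fields left empty).  Optional extra columns ``isotope``
  (default 15N) and ``cluster_id`` are honoured.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .data import DispersionDataset, ExperimentPoint, RateValue, SpinSystem

__all__ = [
    "read_sparky_peak_list",
    "read_dispersion_csv",
    "write_dispersion_csv",
    "PeakListFormatError",
]

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "spin_id",
    "exp_type",
    "field_h1_mhz",
    "nu_cpmg",
    "relax_time_T",
    "omega1",
    "offset_ppm",
    "r1",
    "r2eff",
    "r2eff_err",
]


class PeakListFormatError(ValueError):
    """Raised when a peak list contains no parseable peak rows."""


def read_sparky_peak_list(path: str | Path) -> dict[str, float]:
    """Read a Sparky-style peak list, returning intensity by assignment.

    The last whitespace-separated token of each row is taken as the peak
    height; the first as the assignment.  Header lines (starting with
    "Assignment" or containing no numeric height) and unparseable rows are
    skipped with a log message.  Duplicate assignments: last occurrence
    wins, with a warning.
    """
    path = Path(path)
    text = path.read_text()
    intensities: dict[str, float] = {}
    n_rows = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 2:
            continue
        if tokens[0].lower() == "assignment":
            continue
        try:
            height = float(tokens[-1])
        except ValueError:
            log.info("%s:%d: skipping unparseable row %r", path, lineno, line)
            continue
        assignment = tokens[0]
        try:
            float(assignment)
        except ValueError:
            pass
        else:
            log.info("%s:%d: skipping row with numeric assignment", path, lineno)
            continue
        if assignment in intensities:
            log.warning(
                "%s:%d: duplicate assignment %r, keeping the last value",
                path,
                lineno,
                assignment,
            )
        intensities[assignment] = height
        n_rows += 1
    if n_rows == 0:
        raise PeakListFormatError(f"{path}: no parseable peak rows")
    return intensities


def _opt(value: object) -> float | None:
    if value is None:
        return None
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def read_dispersion_csv(path: str | Path) -> DispersionDataset:
    """Load a generic CSV dispersion table into a dataset."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    spins: dict[str, SpinSystem] = {}
    points: list[ExperimentPoint] = []
    point_index: dict[ExperimentPoint, int] = {}
    values: dict[tuple[str, int], RateValue] = {}
    for row in df.itertuples(index=False):
        sid = str(row.spin_id)
        isotope = str(getattr(row, "isotope", "15N") or "15N")
        if isotope in ("nan", ""):
            isotope = "15N"
        cluster = getattr(row, "cluster_id", None)
        if cluster is not None and (
            (isinstance(cluster, float) and math.isnan(cluster)) or cluster == ""
        ):
            cluster = None
        if sid not in spins:
            spins[sid] = SpinSystem(
                spin_id=sid,
                isotope=isotope,
                cluster_id=None if cluster is None else str(cluster),
            )
        pt = ExperimentPoint(
            exp_type=str(row.exp_type),
            field_h1_mhz=float(row.field_h1_mhz),
            nu_cpmg=_opt(row.nu_cpmg),
            relax_time_T=_opt(row.relax_time_T),
            omega1=_opt(row.omega1),
            offset=_opt(row.offset_ppm),
            r1=_opt(row.r1),
        )
        idx = point_index.setdefault(pt, len(points))
        if idx == len(points):
            points.append(pt)
        values[(sid, idx)] = RateValue(
            value=float(row.r2eff), error=float(row.r2eff_err)
        )
    return DispersionDataset(list(spins.values()), points, values)


def write_dispersion_csv(dataset: DispersionDataset, path: str | Path) -> None:
    """Write a dataset back out in the generic CSV dialect."""
    rows = []
    for spin in dataset.spins:
        for idx, pt, rv in dataset.iter_spin_values(spin.spin_id):
            rows.append(
                {
                    "spin_id": spin.spin_id,
                    "exp_type": pt.exp_type,
                    "field_h1_mhz": pt.field_h1_mhz,
                    "nu_cpmg": pt.nu_cpmg,
                    "relax_time_T": pt.relax_time_T,
                    "omega1": pt.omega1,
                    "offset_ppm": pt.offset,
                    "r1": pt.r1,
                    "r2eff": rv.value,
                    "r2eff_err": rv.error,
                    "isotope": spin.isotope,
                    "cluster_id": spin.cluster_id,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS + ["isotope", "cluster_id"]).to_csv(
        path, index=False
    )
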