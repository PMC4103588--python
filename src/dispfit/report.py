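"""Result writers: summary CSV, per-spin curve CSVs, xmgrace plots, log.

The xmgrace writer emits a minimal two-set ``.agr`` file per spin
(observed rates with error bars plus the back-calculated curve of the
chosen model); nothing beyond what xmgrace needs to open the file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_summary_csv", "write_curve_csv", "write_agr", "write_report"]


def write_summary_csv(rows: list[dict], path: Path) -> None:
    """One row per (cluster/spin, model): params, errors, chi2, aic."""
    df = pd.DataFrame(rows)
    lead = [
        c
        for c in (
            "spin_id",
            "cluster_id",
            "model",
            "chosen",
            "chi2",
            "k",
            "n",
            "aic",
            "eliminated",
            "elimination_reason",
            "warm_start_source",
        )
        if c in df.columns
    ]
    rest = [c for c in df.columns if c not in lead]
    df[lead + sorted(rest)].to_csv(path, index=False)


def write_curve_csv(curve_rows: list[dict], path: Path) -> None:
    """Observed vs back-calculated rates for one spin."""
    pd.DataFrame(curve_rows).to_csv(path, index=False)


def write_agr(curve_rows: list[dict], spin_id: str, model: str, path: Path) -> None:
    """A minimal xmgrace file: observed points (dy errors) + fitted curve."""
    is_cpmg = any(r.get("nu_cpmg") is not None for r in curve_rows)
    xlabel = r"\xn\f{}\sCPMG\N (Hz)" if is_cpmg else r"\xw\f{}\s1\N/2\xp\f{} (Hz)"
    lines = [
        "@version 50121",
        f'@    title "{spin_id}"',
        f'@    subtitle "model: {model}"',
        f'@    xaxis label "{xlabel}"',
        '@    yaxis label "R\\s2,eff\\N / R\\s1\\xr\\f{}\\N (s\\S-1\\N)"',
        "@    s0 type xydy",
        '@    s0 symbol 1',
        '@    s0 line type 0',
        '@    s0 legend "observed"',
        "@    s1 type xy",
        '@    s1 legend "back-calculated"',
    ]
    lines.append("@target G0.S0")
    lines.append("@type xydy")
    for r in sorted(curve_rows, key=lambda r: r["x"]):
        lines.append(f"{r['x']:.6g} {r['observed']:.8g} {r['error']:.8g}")
    lines.append("&")
    lines.append("@target G0.S1")
    lines.append("@type xy")
    for r in sorted(curve_rows, key=lambda r: r["x"]):
        lines.append(f"{r['x']:.6g} {r['calculated']:.8g}")
    lines.append("&")
    path.write_text("\n".join(lines) + "\n")


def write_report(report, outdir: str | Path) -> list[Path]:
    """Write a full protocol report; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_path = outdir / "summary.csv"
    write_summary_csv(report.summary_rows(), summary_path)
    written.append(summary_path)

    for spin_id, rows in report.curves.items():
        safe = spin_id.replace(":", "_").replace("/", "_")
        cpath = outdir / f"curves_{safe}.csv"
        write_curve_csv(rows, cpath)
        written.append(cpath)
        apath = outdir / f"dispersion_{safe}.agr"
        chosen = report.chosen_model(spin_id)
        write_agr(rows, spin_id, chosen, apath)
        written.append(apath)

    log_path = outdir / "protocol.log"
    log_path.write_text("\n".join(report.log_lines) + "\n")
    written.append(log_path)
    return written
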