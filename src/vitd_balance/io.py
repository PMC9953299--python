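"""CSV readers/writers for serum/urine panels and report serialization.

Serum CSV columns: ``sample_id, time_h, metabolite, value, unit``.
Urine CSV columns: ``sample_id, t0_h, t1_h, volume_L, metabolite, value, unit``.
UTF-8, comma-delimited, header row required; the unit column is mandatory
(no default unit is guessed) and every value is converted exactly to the
canonical nmol/L on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import IO, Any

import pandas as pd

from .balance import DemandReport, SerumPanel, SynthesisEstimate, UrineCollection
from .units import Concentration, Unit, convert

__all__ = [
    "read_serum_csv",
    "write_serum_csv",
    "read_urine_csv",
    "write_urine_csv",
    "write_report",
    "report_to_dict",
]

_SERUM_COLS = ["sample_id", "time_h", "metabolite", "value", "unit"]
_URINE_COLS = ["sample_id", "t0_h", "t1_h", "volume_L", "metabolite", "value", "unit"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} CSV is missing required column(s): {missing}")


def _canonical(value: float, unit: str, metabolite: str) -> float:
    return convert(Concentration(float(value), Unit(unit), metabolite), Unit.NMOL_PER_L).value


def read_serum_csv(path: str | Path | IO[str]) -> dict[str, list[SerumPanel]]:
    """Read serum panels grouped by sample_id, one panel per time point,
    ordered by time, concentrations canonicalized to nmol/L."""
    df = pd.read_csv(path)
    _check_columns(df, _SERUM_COLS, "serum")
    out: dict[str, list[SerumPanel]] = {}
    for (sid, t), grp in df.groupby(["sample_id", "time_h"], sort=True):
        conc = {
            r.metabolite: _canonical(r.value, r.unit, r.metabolite)
            for r in grp.itertuples(index=False)
        }
        out.setdefault(str(sid), []).append(SerumPanel(float(t), conc))
    for panels in out.values():
        panels.sort(key=lambda p: p.time)
    return out


def write_serum_csv(panels: dict[str, list[SerumPanel]], path: str | Path | IO[str]) -> None:
    rows = [
        {"sample_id": sid, "time_h": p.time, "metabolite": m, "value": c, "unit": "nmol/L"}
        for sid, plist in panels.items()
        for p in plist
        for m, c in sorted(p.concentrations.items())
    ]
    pd.DataFrame(rows, columns=_SERUM_COLS).to_csv(path, index=False)


def read_urine_csv(path: str | Path | IO[str]) -> dict[str, UrineCollection]:
    """Read 24-h urine collections keyed by sample_id, canonical nmol/L."""
    df = pd.read_csv(path)
    _check_columns(df, _URINE_COLS, "urine")
    out: dict[str, UrineCollection] = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        t0s, t1s, vols = grp["t0_h"].unique(), grp["t1_h"].unique(), grp["volume_L"].unique()
        if len(t0s) != 1 or len(t1s) != 1 or len(vols) != 1:
            raise ValueError(f"urine sample {sid!r} has inconsistent interval/volume rows")
        conc = {
            r.metabolite: _canonical(r.value, r.unit, r.metabolite)
            for r in grp.itertuples(index=False)
        }
        out[str(sid)] = UrineCollection(float(t0s[0]), float(t1s[0]), float(vols[0]), conc)
    return out


def write_urine_csv(collections: dict[str, UrineCollection], path: str | Path | IO[str]) -> None:
    rows = [
        {
            "sample_id": sid, "t0_h": u.t0, "t1_h": u.t1, "volume_L": u.volume,
            "metabolite": m, "value": c, "unit": "nmol/L",
        }
        for sid, u in collections.items()
        for m, c in sorted(u.concentrations.items())
    ]
    pd.DataFrame(rows, columns=_URINE_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report serialization


def report_to_dict(report: "DemandReport | SynthesisEstimate", **provenance: Any) -> dict:
    """Lossless dict form of a report, plus optional provenance keys
    (preset label, beta, f) for the output header."""
    d = dataclasses.asdict(report)
    d["kind"] = type(report).__name__
    if provenance:
        d["parameters"] = provenance
    if isinstance(report, SynthesisEstimate):
        d["interval"] = list(report.interval)
        d["per_24h"] = report.per_24h
    return d


def _render_table(d: dict) -> str:
    lines = [f"# {d['kind']}"]
    params = d.pop("parameters", None)
    for key, val in d.items():
        if key == "kind":
            continue
        lines.append(f"{key:24s} {val}")
    if params:
        lines.append("parameters:")
        for key, val in params.items():
            lines.append(f"  {key:22s} {val}")
    if d.get("negative_flag"):
        lines.append("WARNING: negative synthesis total — assumption violation "
                     "suspected; re-measure or apply a correction factor")
    if d.get("reason"):
        lines.append(f"NOTE: ratio undefined (reason: {d['reason']})")
    return "\n".join(lines) + "\n"


def write_report(
    report: "DemandReport | SynthesisEstimate",
    destination: str | Path | IO[str],
    format: str = "json",
    **provenance: Any,
) -> None:
    """Write a report as round-trippable JSON or a human-readable table."""
    if format not in ("json", "table"):
        raise ValueError(f"unknown format {format!r}; valid: ['json', 'table']")
    d = report_to_dict(report, **provenance)
    text = json.dumps(d, indent=2) + "\n" if format == "json" else _render_table(d)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)
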