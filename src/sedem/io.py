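"""CSV/JSON readers and writers for the pipeline's external interfaces.

Dialects: UTF-8, comma-separated, dot decimal. List-valued cells hold
semicolon-separated numbers; sieve fractions occupy one column per sieve
(``sieve_850 ... sieve_50``) plus ``pan_50``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ParseError
from .indices import IndexReport
from .parameters import RawMeasurements, SieveFractions
from .tablet_qc import TabletBatchQC, TabletReport

LIST_SEP = ";"

SIEVE_APERTURES = (850.0, 600.0, 425.0, 300.0, 250.0, 50.0)
SIEVE_COLUMNS = tuple(f"sieve_{a:g}" for a in SIEVE_APERTURES)
PAN_COLUMN = "pan_50"

MEASUREMENT_SCALAR_COLUMNS = (
    "granule_mass", "bulk_volume", "tapped_volume", "cone_height", "cone_radius",
    "flow_time", "loss_on_drying_pct", "hygroscopicity_pct", "percent_fines",
)
MEASUREMENT_LIST_COLUMNS = (
    "compact_strengths", "effervescence_times", "disint_disk_times", "disint_nodisk_times",
)
MEASUREMENT_COLUMNS = (
    ("batch_id",) + MEASUREMENT_SCALAR_COLUMNS + MEASUREMENT_LIST_COLUMNS
    + SIEVE_COLUMNS + (PAN_COLUMN,)
)

TABLET_SCALAR_COLUMNS = (
    "diameter", "friability_mass_before", "friability_mass_after",
    "peak_area_sample", "peak_area_standard", "media_volume", "sample_volume",
    "label_claim",
)
TABLET_LIST_COLUMNS = (
    "crushing_strengths", "thicknesses", "individual_weights",
    "wetting_times", "disintegration_times",
    "dissolution_times", "dissolution_concentrations",
)
TABLET_COLUMNS = ("trial_id",) + TABLET_SCALAR_COLUMNS + TABLET_LIST_COLUMNS


def format_list(values: Sequence[float]) -> str:
    return LIST_SEP.join(repr(float(v)) for v in values)


def parse_list(cell: str, where: str) -> tuple[float, ...]:
    try:
        return tuple(float(x) for x in str(cell).split(LIST_SEP) if x.strip() != "")
    except ValueError:
        raise ParseError(f"non-numeric list cell at {where}: {cell!r}") from None


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _scalar(row, col: str, where: str) -> Optional[float]:
    v = row[col]
    if pd.isna(v) or v == "":
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ParseError(f"non-numeric cell at {where}, column {col!r}: {v!r}") from None


def read_measurements(path) -> list[RawMeasurements]:
    """Parse a per-batch raw-measurements CSV into validated records."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        where = f"{path}, row {i + 2}"  # 1-based + header line
        kwargs: dict = {"batch_id": str(row["batch_id"])}
        for col in MEASUREMENT_SCALAR_COLUMNS:
            kwargs[col] = _scalar(row, col, where)
        for col in MEASUREMENT_LIST_COLUMNS:
            cell = row[col]
            kwargs[col] = None if pd.isna(cell) else parse_list(cell, where)
        sieve_vals = [_scalar(row, c, where) for c in SIEVE_COLUMNS]
        pan = _scalar(row, PAN_COLUMN, where)
        if any(v is not None for v in sieve_vals) or pan is not None:
            try:
                kwargs["sieve_fractions"] = SieveFractions(
                    fractions=tuple(
                        (a, v if v is not None else 0.0)
                        for a, v in zip(SIEVE_APERTURES, sieve_vals)
                    ),
                    pan_percent=pan if pan is not None else 0.0,
                )
            except Exception as exc:
                raise ParseError(f"invalid sieve fractions at {where}: {exc}") from exc
        try:
            records.append(RawMeasurements(**kwargs))
        except Exception as exc:
            raise ParseError(f"invalid record at {where}: {exc}") from exc
    return records


def write_measurements(records: Sequence[RawMeasurements], path) -> Path:
    rows = []
    for m in records:
        row: dict = {"batch_id": m.batch_id}
        for col in MEASUREMENT_SCALAR_COLUMNS:
            row[col] = getattr(m, col)
        for col in MEASUREMENT_LIST_COLUMNS:
            v = getattr(m, col)
            row[col] = None if v is None else format_list(v)
        if m.sieve_fractions is not None:
            for (aperture, pct), col in zip(m.sieve_fractions.fractions, SIEVE_COLUMNS):
                row[col] = pct
            row[PAN_COLUMN] = m.sieve_fractions.pan_percent
        rows.append(row)
    out = Path(path)
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(out, index=False)
    return out


def read_tablets(path) -> list[TabletBatchQC]:
    """Parse a per-trial tablet QC CSV into validated records."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TABLET_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        where = f"{path}, row {i + 2}"
        kwargs: dict = {"trial_id": str(row["trial_id"])}
        for col in TABLET_SCALAR_COLUMNS:
            v = _scalar(row, col, where)
            if v is not None:
                kwargs[col] = v
        lists: dict[str, tuple[float, ...]] = {}
        for col in TABLET_LIST_COLUMNS:
            cell = row[col]
            lists[col] = () if pd.isna(cell) else parse_list(cell, where)
        for col in ("crushing_strengths", "thicknesses", "individual_weights",
                    "wetting_times", "disintegration_times"):
            kwargs[col] = lists[col]
        times, concs = lists["dissolution_times"], lists["dissolution_concentrations"]
        if len(times) != len(concs):
            raise ParseError(
                f"{where}: dissolution_times ({len(times)}) and "
                f"dissolution_concentrations ({len(concs)}) differ in length"
            )
        kwargs["dissolution_samples"] = tuple(zip(times, concs))
        try:
            records.append(TabletBatchQC(**kwargs))
        except Exception as exc:
            raise ParseError(f"invalid record at {where}: {exc}") from exc
    return records


def write_tablets(records: Sequence[TabletBatchQC], path) -> Path:
    rows = []
    for qc in records:
        row: dict = {"trial_id": qc.trial_id}
        for col in TABLET_SCALAR_COLUMNS:
            row[col] = getattr(qc, col)
        for col in ("crushing_strengths", "thicknesses", "individual_weights",
                    "wetting_times", "disintegration_times"):
            row[col] = format_list(getattr(qc, col))
        row["dissolution_times"] = format_list([t for t, _ in qc.dissolution_samples])
        row["dissolution_concentrations"] = format_list([c for _, c in qc.dissolution_samples])
        rows.append(row)
    out = Path(path)
    pd.DataFrame(rows, columns=list(TABLET_COLUMNS)).to_csv(out, index=False)
    return out


def write_radii(profiles, path, clamped: bool = False) -> Path:
    """One row per batch, one column per parameter id (raw or clamped radii)."""
    rows = []
    for p in profiles:
        values = p.clamped if clamped else dict(p.raw)
        rows.append({"batch_id": p.batch_id, **values})
    out = Path(path)
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def read_radii(path, system: str = "odt"):
    """Inverse of :func:`write_radii` (raw radii)."""
    from .radii import RadiusProfile

    df = pd.read_csv(path)
    _require_columns(df, ("batch_id",), path)
    return [
        RadiusProfile.from_radii(
            str(row["batch_id"]),
            {c: float(row[c]) for c in df.columns if c != "batch_id" and pd.notna(row[c])},
            system,
        )
        for _, row in df.iterrows()
    ]


def index_report_to_dict(report: IndexReport) -> dict:
    return dataclasses.asdict(report)


def index_report_from_dict(d: dict) -> IndexReport:
    return IndexReport(**d)


def write_index_reports(reports: Sequence[IndexReport], path) -> Path:
    out = Path(path)
    out.write_text(
        json.dumps([index_report_to_dict(r) for r in reports], indent=2) + "\n",
        encoding="utf-8",
    )
    return out


def read_index_reports(path) -> list[IndexReport]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [index_report_from_dict(d) for d in data]


def tablet_report_to_dict(report: TabletReport) -> dict:
    d = dataclasses.asdict(report)
    d["dissolution"] = [list(x) for x in d["dissolution"]]
    return d


def write_tablet_reports(reports: Sequence[TabletReport], path) -> Path:
    out = Path(path)
    out.write_text(
        json.dumps([tablet_report_to_dict(r) for r in reports], indent=2) + "\n",
        encoding="utf-8",
    )
    return out


def read_tablet_reports(path) -> list[TabletReport]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for d in data:
        d["dissolution"] = tuple(tuple(x) for x in d["dissolution"])
        out.append(TabletReport(**d))
    return out
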