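"""CSV readers and writers for prescription records, daily series and episodes.

Formats (header required, ISO-8601 dates):

* records:  ``patient_id, drug_code, start_date, end_date[, month, packages]``
  — a row is interval form (start/end filled) or dispensation form
  (month/packages filled), never both;
* daily:    ``patient_id, date, combination``;
* episodes: ``patient_id, combination, start_date, end_date``.

Combinations are serialised in canonical form: sorted codes joined by
``"+"``, the empty combination as ``"NONE"``.  Outputs are sorted by
patient then date so results never depend on processing order.
Malformed record rows are reported with their file line numbers; a file
fails as a whole when more than a configurable fraction of rows is bad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .types import Combination, Episode, ExposureSeries, PrescriptionRecord

logger = logging.getLogger("rxsmooth")

PathLike = Union[str, Path]

RECORD_COLUMNS = ("patient_id", "drug_code", "start_date", "end_date")


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based physical line in the file (header is line 1)
    message: str


def _parse_date(text: str, column: str) -> date:
    try:
        return datetime.strptime(text, "%Y-%m-%d").date()
    except ValueError as exc:
        raise ValueError(f"{column}: unparseable date {text!r}") from exc


def read_prescriptions(
    path: PathLike, max_invalid_fraction: float = 0.0
) -> dict[str, list[PrescriptionRecord]]:
    """Read and validate a records CSV, grouped by patient.

    Invalid rows are logged with their line numbers and skipped; the read
    fails when the invalid fraction exceeds ``max_invalid_fraction``
    (default: any invalid row fails the file).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_dispensation = "month" in df.columns and "packages" in df.columns
    if len(df) == 0:
        logger.warning("%s: no data rows", path)
        return {}

    records: dict[str, list[PrescriptionRecord]] = {}
    errors: list[RowError] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            rowd = row._asdict()
            start_s, end_s = rowd["start_date"].strip(), rowd["end_date"].strip()
            month_s = rowd.get("month", "").strip() if has_dispensation else ""
            packages_s = rowd.get("packages", "").strip() if has_dispensation else ""
            if start_s or end_s:
                rec = PrescriptionRecord(
                    patient_id=rowd["patient_id"],
                    drug_code=rowd["drug_code"],
                    start=_parse_date(start_s, "start_date"),
                    end=_parse_date(end_s, "end_date"),
                )
            else:
                if not (month_s and packages_s):
                    raise ValueError("row has neither interval nor month/packages")
                rec = PrescriptionRecord(
                    patient_id=rowd["patient_id"],
                    drug_code=rowd["drug_code"],
                    dispensation_month=_parse_date(month_s + "-01", "month"),
                    packages=int(packages_s),
                )
            records.setdefault(rec.patient_id, []).append(rec)
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
            logger.error("%s line %d: %s", path, line, exc)

    if errors and len(errors) / len(df) > max_invalid_fraction:
        raise ValueError(
            f"{path}: {len(errors)}/{len(df)} invalid rows "
            f"(first: line {errors[0].line}: {errors[0].message})"
        )
    return records


def write_prescriptions(
    records: Iterable[PrescriptionRecord], path: PathLike
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "drug_code": r.drug_code,
                "start_date": r.start.isoformat() if r.start else "",
                "end_date": r.end.isoformat() if r.end else "",
                "month": r.dispensation_month.strftime("%Y-%m")
                if r.dispensation_month
                else "",
                "packages": r.packages if r.packages is not None else "",
            }
        )
    df = pd.DataFrame(
        rows, columns=[*RECORD_COLUMNS, "month", "packages"]
    ).sort_values(["patient_id", "drug_code", "start_date", "month"], kind="stable")
    df.to_csv(path, index=False)


def write_episodes(episodes: Iterable[Episode], path: PathLike) -> None:
    """Write episodes CSV; read-back reproduces the episodes exactly."""
    rows = [
        {
            "patient_id": e.patient_id,
            "combination": str(e.combination),
            "start_date": e.start.isoformat(),
            "end_date": e.end.isoformat(),
        }
        for e in episodes
    ]
    df = pd.DataFrame(
        rows, columns=["patient_id", "combination", "start_date", "end_date"]
    ).sort_values(["patient_id", "start_date"], kind="stable")
    df.to_csv(path, index=False)


def read_episodes(path: PathLike) -> list[Episode]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Episode(
            patient_id=row.patient_id,
            combination=Combination.parse(row.combination),
            start=_parse_date(row.start_date, "start_date"),
            end=_parse_date(row.end_date, "end_date"),
        )
        for row in df.itertuples(index=False)
    ]


def write_daily(series_list: Iterable[ExposureSeries], path: PathLike) -> None:
    rows = []
    for s in sorted(series_list, key=lambda s: s.patient_id):
        for i, comb in enumerate(s.values):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "date": s.date_of(i).isoformat(),
                    "combination": str(comb),
                }
            )
    pd.DataFrame(rows, columns=["patient_id", "date", "combination"]).to_csv(
        path, index=False
    )


def read_daily(path: PathLike) -> list[ExposureSeries]:
    """Read a daily CSV back into per-patient series (days must be gap-free)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        dates = [_parse_date(d, "date") for d in grp["date"]]
        order = sorted(range(len(dates)), key=lambda i: dates[i])
        dates = [dates[i] for i in order]
        values = [Combination.parse(grp["combination"].iloc[i]) for i in order]
        for a, b in zip(dates, dates[1:]):
            if (b - a).days != 1:
                raise ValueError(f"{pid}: daily series has a gap between {a} and {b}")
        out.append(ExposureSeries(str(pid), dates[0], tuple(values)))
    return out
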