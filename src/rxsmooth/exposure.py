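"""Expand raw prescription intervals into daily exposure and back.

This is the data-mining step that precedes any smoothing: every
prescription interval is rasterised to days, all drugs active on the same
day are merged into one :class:`~rxsmooth.types.Combination`, and the
resulting day-level series can be run-length encoded into episodes.

Conventions: intervals are inclusive on both ends; the series spans the
patient's first to last active day; interior days covered by no
prescription are the explicit ``NONE`` combination (they are a category
of their own, visible to the smoothing algorithms); days before the first
or after the last active day are outside the series.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable, Sequence

from .types import NONE, Combination, Episode, ExposureSeries, PrescriptionRecord


def resolve_dispensation(
    record: PrescriptionRecord, days_per_package: int = 30
) -> PrescriptionRecord:
    """Turn a dispensation-form record into an interval-form record.

    Dispensation data carry only the invoice month and the number of
    packages collected; the treatment end must be inferred.  The interval
    starts on the first day of the invoice month and lasts
    ``packages * days_per_package`` days.

    Parameters
    ----------
    record
        A dispensation-form record (month + packages).
    days_per_package
        Assumed days of treatment covered by one package.  30 by default;
        analysts may override per drug class.
    """
    if not record.is_dispensation:
        raise ValueError("record is already interval-form")
    if days_per_package < 1:
        raise ValueError("days_per_package must be a positive integer")
    assert record.dispensation_month is not None and record.packages is not None
    start = record.dispensation_month
    end = start + timedelta(days=record.packages * days_per_package - 1)
    return PrescriptionRecord(
        patient_id=record.patient_id,
        drug_code=record.drug_code,
        start=start,
        end=end,
    )


def expand_to_daily(records: Iterable[PrescriptionRecord]) -> ExposureSeries:
    """Build the per-day combination series for one patient.

    For each day from the earliest start to the latest end, the day's
    combination is the set of drug codes whose interval covers that day.
    Duplicate or overlapping records of the same drug contribute the drug
    once, so the expansion is invariant under record duplication and under
    splitting one interval into adjacent intervals of the same drug.

    An empty record collection yields the empty-series sentinel
    (``origin=None``, no values).
    """
    recs = list(records)
    if not recs:
        return ExposureSeries(patient_id="", origin=None, values=())
    patient_ids = {r.patient_id for r in recs}
    if len(patient_ids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(patient_ids)}")
    if any(r.is_dispensation for r in recs):
        raise ValueError(
            "dispensation-form record present; resolve_dispensation() first"
        )
    origin = min(r.start for r in recs)  # type: ignore[type-var]
    last = max(r.end for r in recs)  # type: ignore[type-var]
    n = (last - origin).days + 1
    day_sets: list[set[str]] = [set() for _ in range(n)]
    for r in recs:
        lo = (r.start - origin).days  # type: ignore[operator]
        hi = (r.end - origin).days  # type: ignore[operator]
        for i in range(lo, hi + 1):
            day_sets[i].add(r.drug_code)
    values = tuple(
        Combination(frozenset(s)) if s else NONE for s in day_sets
    )
    return ExposureSeries(patient_ids.pop(), origin, values)


def collapse_to_episodes(series: ExposureSeries) -> list[Episode]:
    """Run-length encode a daily series into maximal constant episodes.

    Concatenating the returned episodes day-by-day reproduces the series
    exactly; consecutive episodes are date-adjacent and differ in
    combination.
    """
    if len(series) == 0:
        return []
    assert series.origin is not None
    episodes: list[Episode] = []
    run_start = 0
    for i in range(1, len(series) + 1):
        if i == len(series) or series[i] != series[run_start]:
            episodes.append(
                Episode(
                    patient_id=series.patient_id,
                    combination=series[run_start],
                    start=series.date_of(run_start),
                    end=series.date_of(i - 1),
                )
            )
            run_start = i
    return episodes


def episodes_to_series(
    patient_id: str, episodes: Sequence[Episode]
) -> ExposureSeries:
    """Inverse of :func:`collapse_to_episodes` for a gap-free episode list."""
    if not episodes:
        return ExposureSeries(patient_id=patient_id, origin=None, values=())
    eps = sorted(episodes, key=lambda e: e.start)
    origin = eps[0].start
    values: list[Combination] = []
    cursor = origin
    for e in eps:
        if e.start != cursor:
            raise ValueError(f"episodes not date-adjacent at {e.start}")
        values.extend([e.combination] * e.n_days)
        cursor = e.end + timedelta(days=1)
    return ExposureSeries(patient_id, origin, tuple(values))


def truncate_atc(records: Iterable[PrescriptionRecord], level_chars: int) -> list[PrescriptionRecord]:
    """Optional pre-processing: truncate drug codes to the first N characters.

    ATC levels map to prefix lengths (1, 3, 4, 5, 7).  Truncation is never
    applied implicitly; analyses mixing ATC levels should call this
    explicitly before expansion.
    """
    if level_chars < 1:
        raise ValueError("level_chars must be >= 1")
    out = []
    for r in records:
        out.append(
            PrescriptionRecord(
                patient_id=r.patient_id,
                drug_code=r.drug_code[:level_chars],
                start=r.start,
                end=r.end,
                dispensation_month=r.dispensation_month,
                packages=r.packages,
            )
        )
    return out
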