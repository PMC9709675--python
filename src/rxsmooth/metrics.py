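"""Smoothing-impact statistics, the Wt-grid simulation harness, and the
chi-square power computation used for validation-study sample sizing.

The headline impact statistic is the *percent smoothed* for one patient:

    100 x (number of days changed by the algorithm)
        / (total days under active prescription in the original series)

where "active" means a non-empty combination.  Days changed counts every
differing day, including changes the algorithm makes to untreated gap
days, so the percentage can exceed 100 for patients with long gaps.
Cohort-level summaries report, per window length, the number of patients
with at least one changed day and the median/IQR of percent smoothed
among those changed patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .smoothing import SmoothParams, smooth
from .types import ExposureSeries, check_comparable

#: Window grid used by the simulation harness by default (days).
DEFAULT_WT_GRID: tuple[int, ...] = (10, 20, 30, 45, 60, 90)


@dataclass(frozen=True)
class SmoothReport:
    """Per-patient impact of a transformation on the daily series."""

    patient_id: str
    days_changed: int
    active_days: int
    percent_smoothed: float

    @property
    def changed_flag(self) -> bool:
        return self.days_changed >= 1


def compare_series(original: ExposureSeries, transformed: ExposureSeries) -> SmoothReport:
    """Day-wise comparison of an original series with its transform.

    Series must share origin and length.  ``active_days`` is counted on
    the original series and must be positive (a series with no treated
    day has no meaningful denominator).
    """
    check_comparable(original, transformed)
    days_changed = sum(
        1 for a, b in zip(original.values, transformed.values) if a != b
    )
    active_days = sum(1 for c in original.values if not c.is_none)
    if active_days == 0:
        raise ValueError("original series has no days under active prescription")
    return SmoothReport(
        patient_id=original.patient_id,
        days_changed=days_changed,
        active_days=active_days,
        percent_smoothed=100.0 * days_changed / active_days,
    )


@dataclass(frozen=True)
class SimulationSummary:
    """Per-window-length aggregate of smoothing impact over a cohort.

    ``table`` columns: ``wt, n_patients, n_changed, prop_changed,
    pct_smoothed_median, pct_smoothed_q1, pct_smoothed_q3`` — quantiles
    of percent smoothed among changed patients (NaN when none changed),
    computed with the linear-interpolation (type-7) convention.
    """

    table: pd.DataFrame
    reports: dict[int, list[SmoothReport]]


def run_simulation(
    cohort: Iterable[ExposureSeries],
    wt_grid: Sequence[int] = DEFAULT_WT_GRID,
) -> SimulationSummary:
    """Smooth every patient at every window length and aggregate impact.

    Deterministic given its inputs: patients are processed independently
    and the summary does not depend on cohort order beyond the stated
    aggregates.
    """
    patients = list(cohort)
    if not patients:
        raise ValueError("cohort must be non-empty")
    if not wt_grid:
        raise ValueError("wt_grid must be non-empty")
    rows = []
    all_reports: dict[int, list[SmoothReport]] = {}
    for wt in wt_grid:
        params = SmoothParams(wt=wt)
        reports = [compare_series(s, smooth(s, params)) for s in patients]
        all_reports[wt] = reports
        changed = [r.percent_smoothed for r in reports if r.changed_flag]
        if changed:
            q1, med, q3 = np.percentile(changed, [25, 50, 75])  # type-7
        else:
            q1 = med = q3 = float("nan")
        rows.append(
            {
                "wt": wt,
                "n_patients": len(reports),
                "n_changed": len(changed),
                "prop_changed": len(changed) / len(reports),
                "pct_smoothed_median": med,
                "pct_smoothed_q1": q1,
                "pct_smoothed_q3": q3,
            }
        )
    return SimulationSummary(table=pd.DataFrame(rows), reports=all_reports)


def chi_square_power(w: float, df: int, alpha: float, n: int) -> float:
    """Power of the chi-square test at effect size ``w`` and sample size ``n``.

    Cohen's effect size ``w`` yields noncentrality ``lambda = n * w**2``;
    power is the probability that a noncentral chi-square variable with
    ``df`` degrees of freedom exceeds the central chi-square critical
    value at level ``alpha``.  At ``w = 0`` this reduces to ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if df < 1:
        raise ValueError("df must be a positive integer")
    if n < 1:
        raise ValueError("n must be a positive integer")
    if w < 0:
        raise ValueError("effect size w must be non-negative")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    nc = n * w * w
    if nc == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, nc))


def min_n_for_power(
    w: float, df: int, alpha: float, target_power: float = 0.80
) -> int:
    """Smallest sample size reaching ``target_power`` at effect size ``w``.

    Power is strictly increasing in ``n`` for ``w > 0``, so a bracketed
    doubling search followed by bisection is exact.
    """
    if w <= 0:
        raise ValueError("w must be positive to reach power above alpha")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie strictly between 0 and 1")
    hi = 1
    while chi_square_power(w, df, alpha, hi) < target_power:
        hi *= 2
        if hi > 10**9:
            raise RuntimeError("sample size search failed to bracket")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if chi_square_power(w, df, alpha, mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
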