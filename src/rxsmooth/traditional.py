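"""Persistence-threshold comparator ("traditional method").

The common literature approach to noisy prescription series: start with
the first observed treatment and accept a treatment change only when the
new combination persists for at least a minimum number of days;
shorter-lived deviations are rewritten to the incumbent treatment.
Typical thresholds are 60 days for chronic medication and 15 days for
short-course drugs such as systemic antibiotics.

A run truncated by the end of follow-up cannot have its persistence
judged; rewriting it would fabricate exposure beyond the observed data,
so a terminal run shorter than the threshold IS accepted as a change and
flagged as censored in :class:`TraditionalResult`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import ExposureSeries


@dataclass(frozen=True)
class TraditionalParams:
    """Minimum persistence (days) required to accept a treatment change."""

    min_duration: int

    def __post_init__(self) -> None:
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")


#: Conventional thresholds: chronic treatment vs short-course antibiotics.
CHRONIC = TraditionalParams(min_duration=60)
ANTIBIOTIC = TraditionalParams(min_duration=15)


@dataclass(frozen=True)
class TraditionalResult:
    series: ExposureSeries
    #: True when the last accepted change was a terminal run shorter than
    #: min_duration (persistence unjudgeable — censored by end of follow-up).
    tail_censored: bool


def apply_traditional(
    series: ExposureSeries, params: TraditionalParams
) -> TraditionalResult:
    """Left-to-right persistence scan, with censoring metadata.

    Maintains an accepted combination (initialised to day 0's value).  On
    meeting a day that differs, the maximal run of the new combination
    starting there is measured: if it lasts at least ``min_duration`` days
    — or reaches the end of follow-up — the change is accepted from that
    day; otherwise the whole run is rewritten to the incumbent.  Runs are
    of exact combinations: a run interrupted by a single different day
    counts as two runs, each judged independently.
    """
    n = len(series)
    if n == 0:
        return TraditionalResult(series, tail_censored=False)
    values = series.values
    out = list(values)
    accepted = values[0]
    tail_censored = False
    i = 0
    while i < n:
        if values[i] == accepted:
            i += 1
            continue
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        run_len = j - i + 1
        if run_len >= params.min_duration:
            accepted = values[i]
        elif j == n - 1:
            # terminal run, too short to judge: accept, flag censored
            accepted = values[i]
            tail_censored = True
        else:
            for k in range(i, j + 1):
                out[k] = accepted
        i = j + 1
    return TraditionalResult(series.with_values(out), tail_censored)


def traditional(series: ExposureSeries, params: TraditionalParams) -> ExposureSeries:
    """Persistence-threshold rewrite of a daily series (series only)."""
    return apply_traditional(series, params).series
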