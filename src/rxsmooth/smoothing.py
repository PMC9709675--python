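"""The *smooth* algorithm: two-pass sliding-window mode filtering.

Noisy electronic prescription data produce daily treatment-combination
series full of short spurious states — one-day overlaps from early
refills, brief gaps between dispensations, duplicate records.  The smooth
algorithm estimates the most likely therapy on each day by a categorical
analogue of a moving average:

**Pass 1 (window mode).**  A window of ``wt`` days starts at the first
day of follow-up and slides forward one day at a time.  Each window is
assigned the combination occupying the most days inside it; when two or
more combinations tie for the maximum, the previous window's assignment
is carried forward.  Every day thereby accrues up to ``wt`` *candidate*
assignments, one from each window covering it.

**Pass 2 (candidate vote).**  Each day's final combination is the
candidate most frequently observed for that day; ties prefer the previous
day's final choice when it is among the tied candidates, otherwise the
tied candidate produced by the earliest window.

``wt`` is the single tunable parameter.  ``wt = 1`` leaves the data
untouched; ``wt`` equal to the follow-up length collapses the series to
its most frequent combination.  Untreated stretches (the ``NONE``
combination) are a first-class category and are smoothed like any other.
The algorithm is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Hashable, Optional, Sequence, TypeVar

from .types import Combination, ExposureSeries

T = TypeVar("T", bound=Hashable)


@dataclass(frozen=True)
class SmoothParams:
    """Window length ``wt`` in days (>= 1).

    Values of 30–60 days are a reasonable default range for chronic
    medication; short-course drugs (e.g. systemic antibiotics) call for
    smaller windows.  ``wt`` larger than the series length degrades to a
    single window spanning the whole series.
    """

    wt: int

    def __post_init__(self) -> None:
        if self.wt < 1:
            raise ValueError("wt must be a positive number of days")


@dataclass(frozen=True)
class CandidateMatrix:
    """Pass-1 output: one assignment per window, plus series metadata.

    Window ``k`` covers days ``k .. k + wt - 1``; the candidates for day
    ``i`` are the assignments of all windows covering ``i`` (between 1 at
    the series edges and ``wt`` in the interior), ordered by window index.
    """

    patient_id: str
    origin: Optional[date]
    n_days: int
    wt: int  # effective window length (min(requested wt, n_days))
    assignments: tuple[Combination, ...]

    @property
    def n_windows(self) -> int:
        return len(self.assignments)

    def window_range(self, day: int) -> tuple[int, int]:
        """Inclusive range of window indices covering ``day``."""
        lo = max(0, day - self.wt + 1)
        hi = min(day, self.n_windows - 1)
        return lo, hi

    def candidates(self, day: int) -> tuple[Combination, ...]:
        """Candidates for one day, in increasing window order."""
        lo, hi = self.window_range(day)
        return self.assignments[lo : hi + 1]


def _select_mode(
    window: Sequence[T], previous: Optional[T], has_previous: bool
) -> T:
    """Most frequent value in ``window``; ties carry ``previous`` forward.

    With no previous assignment (the first window), a tie resolves to the
    tied value whose first occurrence in the window is earliest.
    """
    counts: dict[T, int] = {}
    for v in window:  # dict insertion order == first-occurrence order
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    if has_previous:
        return previous  # type: ignore[return-value]
    return tied[0]  # earliest first occurrence


def window_mode(
    window: Sequence[Combination], previous: Optional[Combination] = None
) -> Combination:
    """Pass-1 assignment rule for a single window.

    Returns the combination occupying the most days in ``window``.  On a
    tie the previous window's assignment is carried forward; with no
    previous assignment the tied combination appearing earliest wins.

    ``previous=None`` means "absent" — the first window of a series.
    """
    if len(window) == 0:
        raise ValueError("window must be non-empty")
    return _select_mode(window, previous, previous is not None)


def pass1_candidates(series: ExposureSeries, params: SmoothParams) -> CandidateMatrix:
    """Slide the window over the series and record each window's mode.

    Windows are full length only, starting at days ``0 .. N - wt``; the
    edges of follow-up therefore accrue fewer than ``wt`` candidates.
    When the series is shorter than ``wt`` a single window of the full
    series length is used.
    """
    n = len(series)
    if n == 0:
        raise ValueError("cannot smooth an empty series")
    wt = min(params.wt, n)
    values = series.values
    assignments: list[Combination] = []
    prev: Optional[Combination] = None
    for k in range(n - wt + 1):
        a = _select_mode(values[k : k + wt], prev, prev is not None)
        assignments.append(a)
        prev = a
    return CandidateMatrix(
        patient_id=series.patient_id,
        origin=series.origin,
        n_days=n,
        wt=wt,
        assignments=tuple(assignments),
    )


def pass2_vote(candidates: CandidateMatrix) -> ExposureSeries:
    """Per-day majority vote over the pass-1 candidates.

    Ties prefer (1) the previous day's final choice if it is among the
    tied candidates, else (2) the tied candidate first produced by the
    earliest window — dict insertion order over candidates listed in
    window order gives exactly that.
    """
    final: list[Combination] = []
    for i in range(candidates.n_days):
        cands = candidates.candidates(i)
        if not cands:
            raise ValueError(f"day {i} has no candidates")
        counts: dict[Combination, int] = {}
        for c in cands:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        tied = [c for c, n in counts.items() if n == best]
        if len(tied) == 1:
            final.append(tied[0])
        elif i > 0 and final[i - 1] in tied:
            final.append(final[i - 1])
        else:
            final.append(tied[0])
    return ExposureSeries(candidates.patient_id, candidates.origin, tuple(final))


def smooth(series: ExposureSeries, params: SmoothParams) -> ExposureSeries:
    """Estimate the most likely daily therapy: pass 2 applied to pass 1.

    The output series has the same patient, origin and length as the
    input, and every output combination occurs somewhere in the input.
    """
    return pass2_vote(pass1_candidates(series, params))
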