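"""Core domain types for longitudinal drug-exposure modelling.

The vocabulary follows pharmacoepidemiology practice: a *prescription
record* is one interval during which one drug is prescribed or dispensed;
a *treatment combination* is the exact set of drugs a patient is exposed
to on a given calendar day (the empty set meaning "no active treatment");
an *exposure series* is the day-by-day sequence of combinations over a
patient's follow-up; an *episode* is a maximal run of consecutive days
with an identical combination, the analysis-ready rendering of therapy
over time.

All date intervals are inclusive on both ends and have one-day
resolution.  Drug codes are opaque strings (typically ATC codes at an
analyst-chosen level, e.g. ``"C09AA"``); no ontology logic is applied
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Iterator, Optional, Sequence


@dataclass(frozen=True, order=True)
class Combination:
    """An exact set of drug codes active on one day.

    Equality is exact set equality: ``A+B``, ``A+B+C`` and ``A`` are three
    distinct therapies.  The canonical string form joins the sorted codes
    with ``"+"``; the empty set renders as ``"NONE"`` and represents a day
    with no active treatment.
    """

    drugs: frozenset[str] = field(compare=False)
    # sort key / canonical form; derived, used for ordering and equality
    _key: str = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for code in self.drugs:
            if not code or "+" in code:
                raise ValueError(f"invalid drug code: {code!r}")
        object.__setattr__(self, "_key", "+".join(sorted(self.drugs)) or "NONE")

    @classmethod
    def of(cls, *codes: str) -> "Combination":
        return cls(frozenset(codes))

    @classmethod
    def parse(cls, text: str) -> "Combination":
        """Inverse of ``str()``: ``"B01AC+C07AB"`` → that two-drug set."""
        text = text.strip()
        if not text or text == "NONE":
            return NONE
        return cls(frozenset(text.split("+")))

    @property
    def is_none(self) -> bool:
        return not self.drugs

    def __str__(self) -> str:
        return self._key

    def __hash__(self) -> int:
        return hash(self._key)


#: Sentinel combination for days with no active treatment.  Gaps inside
#: follow-up are represented explicitly with this value so that untreated
#: stretches participate in smoothing as a first-class category.
NONE = Combination(frozenset())


@dataclass(frozen=True)
class PrescriptionRecord:
    """One raw prescription or dispensation for one drug and one patient.

    Two mutually exclusive forms exist:

    * **interval form** — ``start`` and ``end`` dates (both inclusive);
    * **dispensation form** — ``dispensation_month`` (any date inside the
      invoice month; normalised to its first day) plus a positive
      ``packages`` count, from which an interval is later inferred with
      :func:`rxsmooth.exposure.resolve_dispensation`.
    """

    patient_id: str
    drug_code: str
    start: Optional[date] = None
    end: Optional[date] = None
    dispensation_month: Optional[date] = None
    packages: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.drug_code:
            raise ValueError("drug_code must be a non-empty string")
        interval = self.start is not None or self.end is not None
        dispensed = self.dispensation_month is not None or self.packages is not None
        if interval and dispensed:
            raise ValueError("record cannot be both interval and dispensation form")
        if interval:
            if self.start is None or self.end is None:
                raise ValueError("interval form needs both start and end")
            if self.start > self.end:
                raise ValueError(f"start {self.start} after end {self.end}")
        elif dispensed:
            if self.dispensation_month is None or self.packages is None:
                raise ValueError("dispensation form needs month and packages")
            if self.packages < 1:
                raise ValueError("packages must be >= 1")
            object.__setattr__(
                self, "dispensation_month", self.dispensation_month.replace(day=1)
            )
        else:
            raise ValueError("record needs either start/end or month/packages")

    @property
    def is_dispensation(self) -> bool:
        return self.dispensation_month is not None

    @property
    def n_days(self) -> int:
        if self.is_dispensation:
            raise ValueError("dispensation record has no resolved length")
        assert self.start is not None and self.end is not None
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class ExposureSeries:
    """Day-indexed sequence of treatment combinations for one patient.

    Day index ``i`` corresponds to calendar date ``origin + i`` days; the
    index has no gaps.  ``origin`` is ``None`` only for the empty series
    (the sentinel returned when a patient has no records).
    """

    patient_id: str
    origin: Optional[date]
    values: tuple[Combination, ...]

    def __post_init__(self) -> None:
        if self.values and self.origin is None:
            raise ValueError("non-empty series requires an origin date")
        if not isinstance(self.values, tuple):
            object.__setattr__(self, "values", tuple(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[Combination]:
        return iter(self.values)

    def __getitem__(self, i: int) -> Combination:
        return self.values[i]

    def date_of(self, i: int) -> date:
        if self.origin is None:
            raise IndexError("empty series has no dates")
        return self.origin + timedelta(days=i)

    @property
    def end(self) -> Optional[date]:
        if self.origin is None:
            return None
        return self.origin + timedelta(days=len(self.values) - 1)

    def with_values(self, values: Iterable[Combination]) -> "ExposureSeries":
        """Same patient and origin, new per-day values (length-preserving ops)."""
        return ExposureSeries(self.patient_id, self.origin, tuple(values))

    def reindex(self, origin: date, n_days: int, fill: Combination = NONE) -> "ExposureSeries":
        """Project onto the window ``origin .. origin + n_days - 1``.

        Days outside this series' span are filled with ``fill`` (default
        ``NONE``).  Used to align an estimated series with a ground-truth
        window before day-wise comparison.
        """
        if n_days < 1:
            raise ValueError("n_days must be >= 1")
        out: list[Combination] = []
        for i in range(n_days):
            day = origin + timedelta(days=i)
            if self.origin is not None and self.origin <= day <= self.end:  # type: ignore[operator]
                out.append(self.values[(day - self.origin).days])
            else:
                out.append(fill)
        return ExposureSeries(self.patient_id, origin, tuple(out))


@dataclass(frozen=True)
class Episode:
    """Maximal run of consecutive days with one identical combination."""

    patient_id: str
    combination: Combination
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"episode start {self.start} after end {self.end}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def series_equal(a: ExposureSeries, b: ExposureSeries) -> bool:
    return a.origin == b.origin and a.values == b.values


def check_comparable(a: ExposureSeries, b: ExposureSeries) -> None:
    """Raise unless two series share origin and length (day-wise comparable)."""
    if len(a) != len(b) or a.origin != b.origin:
        raise ValueError(
            f"series not comparable: origin {a.origin}/{b.origin}, "
            f"length {len(a)}/{len(b)}"
        )
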