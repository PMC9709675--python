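"""Synthetic prescription cohorts with known ground truth.

Real primary-care dispensation data are not redistributable, so testing
and calibration run on simulated cohorts that emulate their statistical
structure: each patient follows a known regimen plan (segments of mono-
or combination therapy, e.g. an ACE inhibitor, then ACE inhibitor +
beta-blocker, then a triple combination with a statin), realised as
~30-day refill prescriptions, onto which independent noise mechanisms
typical of electronic prescription records are applied:

* **refill gaps** — days shaved off the start of a refill (late pick-up);
* **overlap jitter** — refill end extended past the next refill's start
  (early pick-up), producing overlapping records;
* **duplicate records** — the same prescription emitted twice;
* **spurious prescriptions** — short extra records of a random drug.

The generator returns both the noisy records and the clean ground-truth
daily series, enabling day-level recovery scoring of any estimator.
Randomness is fully reproducible: one stream per cohort, with per-patient
substreams keyed by (seed, patient index), so a given patient's data do
not depend on cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .types import Combination, ExposureSeries, PrescriptionRecord, check_comparable

#: ATC codes of the default chronic cardiovascular alphabet:
#: low-dose aspirin, a statin, a beta-blocker, an ACE inhibitor.
DEFAULT_ALPHABET: tuple[str, ...] = ("B01AC06", "C10AA05", "C07AB07", "C09AA02")

#: Calendar anchor for simulated cohorts (day 0 for every patient).
COHORT_ORIGIN = date(2018, 1, 1)

RegimenPlan = tuple[tuple[frozenset[str], tuple[int, int]], ...]


def default_regimen_plan(
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
) -> RegimenPlan:
    """Chronic polypharmacy course: mono → dual → triple therapy.

    Duration ranges (days) are typical of long-term cardiovascular
    treatment intensification over a two-to-three-year follow-up.
    """
    a, b, c = alphabet[0], alphabet[1], alphabet[2]
    return (
        (frozenset({a}), (120, 240)),
        (frozenset({a, b}), (180, 300)),
        (frozenset({a, b, c}), (120, 240)),
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Rates and sizes of the record-level noise mechanisms.

    Rates are expected counts per patient (Poisson) except
    ``duplicate_rate``, a per-record Bernoulli probability.  Duration
    ranges are inclusive in days.  All mechanisms are independent.
    """

    spurious_rate: float = 2.0
    spurious_duration: tuple[int, int] = (1, 7)
    gap_rate: float = 4.0
    gap_duration: tuple[int, int] = (1, 7)
    duplicate_rate: float = 0.10
    overlap_jitter: int = 5

    def __post_init__(self) -> None:
        if min(self.spurious_rate, self.gap_rate, self.duplicate_rate) < 0:
            raise ValueError("noise rates must be non-negative")
        if self.overlap_jitter < 0:
            raise ValueError("overlap_jitter must be non-negative")
        for lo, hi in (self.spurious_duration, self.gap_duration):
            if not 1 <= lo <= hi:
                raise ValueError("duration ranges must be positive and ordered")


NOISELESS = NoiseSpec(
    spurious_rate=0.0, gap_rate=0.0, duplicate_rate=0.0, overlap_jitter=0
)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a simulated cohort.

    ``regimen_plan`` lists (combination, (min_days, max_days)) segments;
    each patient draws one duration per segment and follows the segments
    back to back from day 0.  The maximal total duration must fit inside
    ``follow_up_days``.
    """

    n_patients: int = 200
    follow_up_days: int = 900
    drug_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    regimen_plan: RegimenPlan = field(default_factory=default_regimen_plan)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    refill_days: int = 30
    #: fraction of records re-emitted in dispensation (month+packages) form
    dispensation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.follow_up_days < 1:
            raise ValueError("n_patients and follow_up_days must be positive")
        if not self.drug_alphabet:
            raise ValueError("drug_alphabet must be non-empty")
        if not self.regimen_plan:
            raise ValueError("regimen_plan must have at least one segment")
        worst = sum(hi for _, (_, hi) in self.regimen_plan)
        if worst > self.follow_up_days:
            raise ValueError(
                f"regimen durations (up to {worst} d) exceed follow-up "
                f"({self.follow_up_days} d)"
            )
        for _, (lo, hi) in self.regimen_plan:
            if not 1 <= lo <= hi:
                raise ValueError("segment duration ranges must be positive")
        if not 0.0 <= self.dispensation_fraction <= 1.0:
            raise ValueError("dispensation_fraction must lie in [0, 1]")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # substream keyed by (seed, patient index): stable under cohort resizing
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _randint(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def generate_patient(
    spec: CohortSpec, index: int
) -> tuple[list[PrescriptionRecord], ExposureSeries]:
    """Noisy records and clean ground truth for one patient."""
    rng = _patient_rng(spec.seed, index)
    pid = f"P{index:05d}"

    # --- ground truth: regimen segments laid back to back from day 0
    durations = [_randint(rng, lo, hi) for _, (lo, hi) in spec.regimen_plan]
    truth_values: list[Combination] = []
    segments: list[tuple[frozenset[str], int, int]] = []  # (drugs, start, end)
    day = 0
    for (drugs, _), d in zip(spec.regimen_plan, durations):
        segments.append((drugs, day, day + d - 1))
        truth_values.extend([Combination(drugs)] * d)
        day += d
    truth = ExposureSeries(pid, COHORT_ORIGIN, tuple(truth_values))

    # --- clean refill records tiling each segment drug by drug
    intervals: list[tuple[str, int, int]] = []  # (drug, start_day, end_day)
    for drugs, seg_lo, seg_hi in segments:
        for drug in sorted(drugs):
            start = seg_lo
            while start <= seg_hi:
                end = min(start + spec.refill_days - 1, seg_hi)
                intervals.append((drug, start, end))
                start = end + 1

    # --- noise: gaps, overlap jitter, duplicates, spurious records
    ns = spec.noise
    n_gaps = int(rng.poisson(ns.gap_rate)) if ns.gap_rate > 0 else 0
    for _ in range(n_gaps):
        if not intervals:
            break
        i = _randint(rng, 0, len(intervals) - 1)
        drug, lo, hi = intervals[i]
        g = _randint(rng, *ns.gap_duration)
        if lo + g > hi:
            intervals.pop(i)  # whole refill missed
        else:
            intervals[i] = (drug, lo + g, hi)

    if ns.overlap_jitter > 0:
        intervals = [
            (drug, lo, hi + _randint(rng, 0, ns.overlap_jitter))
            for drug, lo, hi in intervals
        ]

    n_spurious = int(rng.poisson(ns.spurious_rate)) if ns.spurious_rate > 0 else 0
    for _ in range(n_spurious):
        drug = str(rng.choice(spec.drug_alphabet))
        d = _randint(rng, *ns.spurious_duration)
        start = _randint(rng, 0, max(0, len(truth) - d))
        intervals.append((drug, start, start + d - 1))

    if ns.duplicate_rate > 0:
        dup_flags = rng.random(len(intervals)) < ns.duplicate_rate
        intervals.extend(iv for iv, f in zip(list(intervals), dup_flags) if f)

    records = [
        PrescriptionRecord(
            patient_id=pid,
            drug_code=drug,
            start=COHORT_ORIGIN + timedelta(days=lo),
            end=COHORT_ORIGIN + timedelta(days=hi),
        )
        for drug, lo, hi in intervals
    ]

    if spec.dispensation_fraction > 0:
        converted = []
        for r in records:
            if rng.random() < spec.dispensation_fraction:
                assert r.start is not None
                packages = max(1, round(r.n_days / spec.refill_days))
                converted.append(
                    PrescriptionRecord(
                        patient_id=r.patient_id,
                        drug_code=r.drug_code,
                        dispensation_month=r.start.replace(day=1),
                        packages=packages,
                    )
                )
            else:
                converted.append(r)
        records = converted

    records.sort(key=lambda r: (r.drug_code, r.start or r.dispensation_month))
    return records, truth


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PrescriptionRecord], list[ExposureSeries]]:
    """Generate every patient of a cohort; reproducible from ``spec.seed``."""
    records: list[PrescriptionRecord] = []
    truths: list[ExposureSeries] = []
    for i in range(spec.n_patients):
        recs, truth = generate_patient(spec, i)
        records.extend(recs)
        truths.append(truth)
    return records, truths


def recovery_score(truth: ExposureSeries, estimate: ExposureSeries) -> float:
    """Fraction of days on which the estimated combination equals the truth.

    Series must share origin and length; align with
    :meth:`ExposureSeries.reindex` first when spans differ.
    """
    check_comparable(truth, estimate)
    n = len(truth)
    if n == 0:
        raise ValueError("cannot score empty series")
    hits = sum(1 for a, b in zip(truth.values, estimate.values) if a == b)
    return hits / n


def noiseless(spec: CohortSpec) -> CohortSpec:
    """Copy of a cohort spec with every noise mechanism switched off."""
    return replace(spec, noise=NOISELESS, dispensation_fraction=0.0)
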