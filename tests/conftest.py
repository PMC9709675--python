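"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import random
from datetime import date

import pytest

from rxsmooth import Combination, ExposureSeries, NONE

ORIGIN = date(2019, 1, 1)

A = Combination.of("A")
B = Combination.of("B")
AB = Combination.of("A", "B")
ABC = Combination.of("A", "B", "C")

#: small alphabet used by the random-series builders (incl. untreated days)
ALPHABET = (A, B, AB, NONE)


def make_series(values, patient_id="pt", origin=ORIGIN) -> ExposureSeries:
    return ExposureSeries(patient_id, origin, tuple(values))


def runs(*segments) -> list[Combination]:
    """Build a value list from (combination, length) segments."""
    out = []
    for comb, n in segments:
        out.extend([comb] * n)
    return out


def random_values(rng: random.Random, max_len: int = 60,
                  alphabet=ALPHABET) -> list[Combination]:
    """Random series values with run structure (not i.i.d. noise only).

    Mixes runs of random length with single-day flips so that both the
    smoothing passes and their tie-breaks get exercised.
    """
    n = rng.randint(1, max_len)
    out: list[Combination] = []
    while len(out) < n:
        comb = rng.choice(alphabet)
        run = rng.choice((1, 1, rng.randint(1, 10)))
        out.extend([comb] * run)
    return out[:n]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)
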