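"""The two-pass sliding-window smoother: unit, property and oracle tests."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxsmooth import (
    SmoothParams,
    pass1_candidates,
    pass2_vote,
    smooth,
    window_mode,
)

from conftest import A, AB, ALPHABET, B, make_series, random_values, runs
from oracle import brute_smooth


class TestWindowMode:
    def test_strict_majority_wins(self):
        assert window_mode(runs((A, 6), (B, 4)), previous=B) == A

    def test_tie_carries_previous_forward(self):
        assert window_mode(runs((A, 5), (B, 5)), previous=B) == B

    def test_tie_without_previous_takes_earliest_occurrence(self):
        assert window_mode(runs((A, 5), (B, 5)), previous=None) == A
        assert window_mode([B, A, B, A], previous=None) == B

    def test_previous_carried_even_if_absent_from_window(self):
        # carry-forward is unconditional: the previous treatment wins a
        # draw even when it no longer appears in the current window
        assert window_mode(runs((A, 3), (B, 3)), previous=AB) == AB

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_mode([], previous=A)


class TestPass1:
    def test_single_window_when_wt_equals_length(self):
        cm = pass1_candidates(make_series(runs((A, 5))), SmoothParams(wt=5))
        assert cm.n_windows == 1
        assert all(len(cm.candidates(i)) == 1 for i in range(5))

    def test_candidate_counts_ramp_at_edges(self):
        cm = pass1_candidates(make_series([A] * 10), SmoothParams(wt=3))
        assert cm.n_windows == 8
        counts = [len(cm.candidates(i)) for i in range(10)]
        assert counts == [1, 2, 3, 3, 3, 3, 3, 3, 2, 1]

    def test_constant_series_gives_constant_candidates(self):
        cm = pass1_candidates(make_series([A] * 30), SmoothParams(wt=10))
        assert set(cm.assignments) == {A}

    def test_wt_longer_than_series_degrades_to_one_window(self):
        cm = pass1_candidates(make_series([A, B, A]), SmoothParams(wt=99))
        assert cm.n_windows == 1 and cm.wt == 3


class TestPass2:
    def test_majority_candidate_chosen(self):
        cm = pass1_candidates(make_series(runs((A, 20), (B, 2), (A, 20))),
                              SmoothParams(wt=10))
        out = pass2_vote(cm)
        assert set(out.values) == {A}

    def test_single_candidate_day(self):
        cm = pass1_candidates(make_series([AB] * 4), SmoothParams(wt=4))
        assert pass2_vote(cm).values == (AB,) * 4


class TestSmooth:
    def test_wt1_is_identity(self, rng):
        for _ in range(100):
            s = make_series(random_values(rng))
            assert smooth(s, SmoothParams(wt=1)).values == s.values

    def test_short_deviation_removed(self):
        s = make_series(runs((A, 20), (AB, 3), (A, 20)))
        assert smooth(s, SmoothParams(wt=10)).values == (A,) * 43

    def test_full_length_window_collapses_to_strict_mode(self):
        s = make_series(runs((A, 10), (B, 4), (A, 10), (AB, 6)))
        out = smooth(s, SmoothParams(wt=len(s)))
        assert set(out.values) == {A}

    def test_metadata_preserved(self):
        s = make_series(runs((A, 10), (B, 10)), patient_id="x17")
        out = smooth(s, SmoothParams(wt=4))
        assert (out.patient_id, out.origin, len(out)) == ("x17", s.origin, 20)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SmoothParams(wt=0)
        with pytest.raises(ValueError):
            smooth(make_series([]), SmoothParams(wt=5))

    @given(st.data())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_length_and_closure_invariants(self, data):
        """Output length equals input length and every output combination
        already occurs in the input series."""
        values = data.draw(
            st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=40)
        )
        wt = data.draw(st.integers(1, 45))
        out = smooth(make_series(values), SmoothParams(wt=wt))
        assert len(out) == len(values)
        assert set(out.values) <= set(values)

    @given(st.sampled_from(ALPHABET), st.integers(1, 30), st.integers(1, 35))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_constant_series_is_fixed_point(self, comb, n, wt):
        s = make_series([comb] * n)
        assert smooth(s, SmoothParams(wt=wt)).values == s.values


class TestOracleEquivalence:
    """Production smoother vs the literal brute-force reference."""

    def test_exact_agreement_on_random_series(self):
        rng = random.Random(777)
        for _ in range(300):
            values = random_values(rng, max_len=60)
            wt = rng.randint(1, len(values))
            got = smooth(make_series(values), SmoothParams(wt=wt)).values
            assert list(got) == brute_smooth(values, wt), (values, wt)

    def test_agreement_when_wt_exceeds_length(self):
        rng = random.Random(42)
        for _ in range(50):
            values = random_values(rng, max_len=12)
            wt = len(values) + rng.randint(1, 10)
            got = smooth(make_series(values), SmoothParams(wt=wt)).values
            assert list(got) == brute_smooth(values, wt)


class TestNoiseSuppression:
    @pytest.mark.parametrize("wt", [5, 10])
    def test_guaranteed_removal_threshold(self, wt):
        """A deviant run of length L <= floor((wt-1)/2) embedded anywhere
        in a constant series is always smoothed away."""
        n = 4 * wt
        threshold = (wt - 1) // 2
        for L in range(1, threshold + 1):
            for pos in range(0, n - L + 1):
                values = [A] * n
                values[pos : pos + L] = [B] * L
                out = smooth(make_series(values), SmoothParams(wt=wt))
                assert set(out.values) == {A}, (wt, L, pos)

    def test_long_deviations_can_survive(self):
        # just above half the window, a centred run persists
        wt = 10
        values = runs((A, 20), (B, 8), (A, 20))
        out = smooth(make_series(values), SmoothParams(wt=wt))
        assert B in set(out.values)
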