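"""Independent brute-force reference implementations for cross-checking.

Deliberately literal: nested loops over windows and days, no sliding
counters, no shared code with the package.  Operates on plain Python
sequences of hashable treatment labels.
"""

from __future__ import annotations

from typing import Hashable, Optional, Sequence


def _brute_mode(window: Sequence[Hashable], previous: Optional[Hashable],
                has_previous: bool) -> Hashable:
    # count each distinct value by rescanning the window
    distinct: list[Hashable] = []
    for v in window:
        if v not in distinct:
            distinct.append(v)
    counts = []
    for v in distinct:
        c = 0
        for u in window:
            if u == v:
                c += 1
        counts.append(c)
    best = max(counts)
    tied = [v for v, c in zip(distinct, counts) if c == best]
    if len(tied) == 1:
        return tied[0]
    if has_previous:
        return previous
    # first window: tied value occurring earliest in the window
    for v in window:
        if v in tied:
            return v
    raise AssertionError("unreachable")


def brute_smooth(values: Sequence[Hashable], wt: int) -> list[Hashable]:
    """Two-pass window-mode smoothing, computed the slow obvious way."""
    n = len(values)
    assert n > 0 and wt >= 1
    w = min(wt, n)

    # pass 1: one assignment per window position
    assignments: list[Hashable] = []
    for k in range(n - w + 1):
        window = list(values[k : k + w])
        if k == 0:
            a = _brute_mode(window, None, False)
        else:
            a = _brute_mode(window, assignments[k - 1], True)
        assignments.append(a)

    # pass 2: per-day vote over candidates from every covering window
    final: list[Hashable] = []
    for i in range(n):
        cands: list[Hashable] = []  # in increasing window order
        for k in range(len(assignments)):
            if k <= i <= k + w - 1:
                cands.append(assignments[k])
        distinct: list[Hashable] = []
        for c in cands:
            if c not in distinct:
                distinct.append(c)
        counts = []
        for c in distinct:
            m = 0
            for u in cands:
                if u == c:
                    m += 1
            counts.append(m)
        best = max(counts)
        tied = [c for c, m in zip(distinct, counts) if m == best]
        if len(tied) == 1:
            final.append(tied[0])
        elif i > 0 and final[i - 1] in tied:
            final.append(final[i - 1])
        else:
            # candidate first produced by the earliest window
            for c in cands:
                if c in tied:
                    final.append(c)
                    break
    return final


def brute_traditional(values: Sequence[Hashable], min_duration: int) -> list[Hashable]:
    """Persistence-threshold scan re-derived from its verbal definition."""
    n = len(values)
    if n == 0:
        return []
    out: list[Hashable] = []
    accepted = values[0]
    i = 0
    while i < n:
        if values[i] == accepted:
            out.append(accepted)
            i += 1
            continue
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if (j - i + 1) >= min_duration or j == n - 1:
            accepted = values[i]
            out.extend([accepted] * (j - i + 1))
        else:
            out.extend([accepted] * (j - i + 1))
        i = j + 1
    return out
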