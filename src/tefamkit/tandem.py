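"""Tandem-repeat detection and the uncurated-import prefilter.

Uncurated de novo libraries are contaminated with simple tandem repeats.
Before import, a family consensus is dropped when it is more than 80%
tandemly repetitive AND has less than 100 bp of contiguous non-tandem
sequence — both thresholds strict, so boundary cases are kept.  Detection
uses a period-bounded self-match scan (a functional stand-in for a full
tandem-repeat finder): for each period p up to ``max_period`` the sequence
is compared against itself shifted by p, and windows of high match fraction
spanning at least ``min_copies`` repeat units become tandem intervals.
Periods above ``max_period`` (default 20 bp) are deliberately invisible, so
common and complex satellites survive the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass
class TandemAnnotation:
    """Tandem intervals (0-based half-open) and coverage statistics."""

    intervals: list[tuple[int, int, int, float]]  # (start, end, period, identity)
    tandem_fraction: float
    longest_clear_run: int
    length: int


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_tandem(
    seq: str,
    max_period: int = 20,
    min_identity: float = 0.8,
    min_copies: float = 3.0,
) -> TandemAnnotation:
    """Annotate tandemly repetitive intervals of ``seq``.

    For each period p <= ``max_period``, positions i with
    ``seq[i] == seq[i-p]`` are self-matches; sliding windows of
    ``(min_copies - 1) * p`` match positions with match fraction >=
    ``min_identity`` seed intervals, which are extended left by one period
    (the template copy) and must span at least ``min_copies * p``.
    Overlapping intervals from all periods are merged for the coverage
    statistics.
    """
    if not seq:
        raise ParameterError("sequence must be non-empty")
    s = np.frombuffer(seq.upper().encode(), dtype="S1")
    n = len(s)
    raw: list[tuple[int, int, int, float]] = []
    for p in range(1, min(max_period, n - 1) + 1):
        m = (s[p:] == s[:-p]).astype(float)  # m[i] ~ position i+p
        w = max(int(round((min_copies - 1.0) * p)), p)
        if len(m) < w:
            continue
        c = np.concatenate(([0.0], np.cumsum(m)))
        frac = (c[w:] - c[:-w]) / w  # frac[i]: window m[i:i+w]
        good = frac >= min_identity
        # mark every self-match position covered by a qualifying window
        marked = np.zeros(len(m), dtype=bool)
        idx = np.flatnonzero(good)
        for i in idx:
            marked[i : i + w] = True
        # runs of marked positions
        if not marked.any():
            continue
        d = np.diff(np.concatenate(([0], marked.view(np.int8), [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        # boundary trimming: a run must begin and end with a solid stretch of
        # k consecutive self-matches, so windows straddling a repeat border
        # cannot drag the interval into unique flanking sequence
        k = max(4, p)
        mm = m > 0.5
        solid = np.convolve(mm.astype(int), np.ones(k, dtype=int), mode="valid") == k
        for a, b in zip(starts, ends):
            a, b = int(a), int(b)
            starts_solid = np.flatnonzero(solid[a : max(b - k + 1, a)])
            if len(starts_solid) == 0:
                continue
            a2 = a + int(starts_solid[0])
            b2 = a + int(starts_solid[-1]) + k
            span_start = a2  # position a2+p in seq, minus the template copy p
            span_end = b2 + p
            if span_end - span_start < min_copies * p:
                continue
            ident = float(m[a2:b2].mean())
            if ident < min_identity:
                continue
            raw.append((span_start, span_end, p, ident))
    merged = _merge([(a, b) for a, b, _, _ in raw])
    covered = sum(e - s_ for s_, e in merged)
    # longest contiguous stretch not covered by any tandem interval
    clear = 0
    prev = 0
    for s_, e in merged:
        clear = max(clear, s_ - prev)
        prev = max(prev, e)
    clear = max(clear, n - prev)
    return TandemAnnotation(
        intervals=raw,
        tandem_fraction=covered / n,
        longest_clear_run=clear,
        length=n,
    )


@dataclass
class FilterDecision:
    keep: bool
    tandem_fraction: float
    longest_clear_run: int
    reasons: list[str]


def import_filter(
    fam_consensus: str,
    max_period: int = 20,
    min_identity: float = 0.8,
    min_copies: float = 3.0,
) -> FilterDecision:
    """Apply the uncurated-import rule: drop iff tandem fraction > 0.80 AND
    longest clear run < 100 bp.

    Both inequalities are strict; a family at exactly 80% tandem or exactly
    100 bp clear is kept.  Both conditions are reported either way.
    """
    ann = detect_tandem(fam_consensus, max_period=max_period,
                        min_identity=min_identity, min_copies=min_copies)
    frac_exceeds = ann.tandem_fraction > 0.80
    run_short = ann.longest_clear_run < 100
    reasons = [
        f"tandem_fraction={ann.tandem_fraction:.3f} ({'>' if frac_exceeds else '<='} 0.80)",
        f"longest_clear_run={ann.longest_clear_run} ({'<' if run_short else '>='} 100)",
    ]
    return FilterDecision(
        keep=not (frac_exceeds and run_short),
        tandem_fraction=ann.tandem_fraction,
        longest_clear_run=ann.longest_clear_run,
        reasons=reasons,
    )
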