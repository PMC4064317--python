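"""Brute-force reference implementations used to validate the fast paths.

Everything here is deliberately naive — O(n*m) position scans and exhaustive
run enumeration — and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def overlap_positions(a, b) -> int:
    """Shared integer positions of two half-open intervals on one chromosome."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def arm_of_midpoint(iv, arm_spans: dict) -> str | None:
    mid = (iv.start + iv.end) // 2
    for label, (lo, hi) in arm_spans.items():
        if lo <= mid < hi:
            return label
    return None


def enumerate_segments(ratios, min_probes, min_abs_log2, t):
    """All maximal same-sign threshold-exceeding runs passing both filters.

    Returns (start_index, end_index_inclusive, state, mean) tuples over one
    chromosome's probe ratio vector.
    """
    def sgn(x):
        if np.isnan(x):
            return 0
        if x > t:
            return 1
        if x < -t:
            return -1
        return 0

    n = len(ratios)
    out = []
    for i in range(n):
        for j in range(i, n):
            s = sgn(ratios[i])
            if s == 0 or any(sgn(ratios[k]) != s for k in range(i, j + 1)):
                continue
            # maximality
            if i > 0 and sgn(ratios[i - 1]) == s:
                continue
            if j < n - 1 and sgn(ratios[j + 1]) == s:
                continue
            mean = float(np.mean(ratios[i : j + 1]))
            if (j - i + 1) >= min_probes and abs(mean) >= min_abs_log2:
                out.append((i, j, "loss" if s < 0 else "gain", mean))
    return out


def boundary_breakpoints(seg_spans, probe_spans):
    """Expected breakpoint intervals for loss segments on one chromosome.

    ``seg_spans``: list of (start, end); ``probe_spans``: sorted list of
    (start, end).  Returns a list of (lo, hi) probe-pair union intervals.
    """
    out = []
    for s, e in seg_spans:
        inside = [k for k, (ps, pe) in enumerate(probe_spans) if ps >= s and pe <= e]
        if not inside:
            continue
        first, last = inside[0], inside[-1]
        if first > 0:
            pair = [probe_spans[first - 1], probe_spans[first]]
            out.append((min(p[0] for p in pair), max(p[1] for p in pair)))
        if last < len(probe_spans) - 1:
            pair = [probe_spans[last], probe_spans[last + 1]]
            out.append((min(p[0] for p in pair), max(p[1] for p in pair)))
    return out


def perbase_cbp_regions(intervals, min_support):
    """Maximal regions where >= min_support distinct samples cover a position,
    by literal per-base counting.  ``intervals``: list of (sample, start, end)
    on one chromosome.  Returns [(start, end), ...]."""
    if not intervals:
        return []
    lo = min(s for _, s, _ in intervals)
    hi = max(e for _, _, e in intervals)
    qualifying = []
    for pos in range(lo, hi):
        samples = {smp for smp, s, e in intervals if s <= pos < e}
        qualifying.append(len(samples) >= min_support)
    regions = []
    start = None
    for k, q in enumerate(qualifying):
        if q and start is None:
            start = lo + k
        elif not q and start is not None:
            regions.append((start, lo + k))
            start = None
    if start is not None:
        regions.append((start, hi))
    return regions


def count_overlaps_naive(iv, records) -> int:
    """records: iterable of (chrom, start, end)."""
    return sum(1 for c, s, e in records if c == iv.chrom and s < iv.end and e > iv.start)


def midpoint_bin_naive(windows: pd.DataFrame, reads: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(windows), dtype=int)
    for _, read in reads.iterrows():
        mid = (read["start"] + read["end"]) // 2
        for k, (_, w) in enumerate(windows.iterrows()):
            if w["chrom"] == read["chrom"] and w["start"] <= mid < w["end"]:
                counts[k] += 1
                break
    return counts


def km_product(times, events):
    """Product-limit estimate over the event times, naive risk-set scan."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for t in sorted(set(times)):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        if d > 0:
            s *= 1 - d / at_risk
        out.append((t, s))
    return out


def cox_loglik_binary(beta, times, events, group):
    """Breslow partial log-likelihood for one binary covariate (no ties assumed)."""
    ll = 0.0
    for t, e, g in zip(times, events, group):
        if not e:
            continue
        risk = [(ti, gi) for ti, gi in zip(times, group) if ti >= t]
        ll += beta * g - np.log(sum(np.exp(beta * gi) for _, gi in risk))
    return ll
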