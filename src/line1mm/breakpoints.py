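"""Breakpoint extraction at copy-number-loss boundaries and cohort-level
recurrence (common breakpoints, CBPs).

A breakpoint is the region encompassed by the pair of probes flanking a loss
boundary: the last probe outside the segment and the first probe inside (or
vice versa on the right side).  A boundary at a chromosome end, where no
outside probe exists, yields no breakpoint on that side.  CBPs are maximal
regions where breakpoint intervals from at least ``min_support`` distinct
samples overlap, found by a sweep-line over per-sample merged intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cna import ProbeSet, SegmentCall
from .genome import GenomicInterval

__all__ = ["Breakpoint", "CBP", "extract_breakpoints", "count_breakpoints", "find_cbps"]


@dataclass(frozen=True)
class Breakpoint:
    sample: str
    interval: GenomicInterval
    side: str  # "left" | "right"
    segment: SegmentCall


@dataclass
class CBP:
    """Recurrence-merged breakpoint region (one row of a CBP table).

    ``interval`` is the sweep-line core: every internal position is covered
    by breakpoint intervals from >= min_support distinct samples.
    ``footprint`` is the encompassing region spanned by the supporting
    probe-pair breakpoint intervals; densities are scored on the footprint,
    matching how published CBP spans are reported (probe-pair regions, not
    intersection cores).
    """

    interval: GenomicInterval
    supporting_samples: int
    break_frequency: float  # percent of cohort
    footprint: GenomicInterval | None = None
    genes: tuple[str, ...] = ()
    repeat_density: float | None = None

    @property
    def density_interval(self) -> GenomicInterval:
        return self.footprint if self.footprint is not None else self.interval


def extract_breakpoints(
    segments: list[SegmentCall],
    probes: ProbeSet,
    states: tuple[str, ...] = ("loss",),
) -> list[Breakpoint]:
    """Flanking-probe-pair breakpoints for every segment in ``states``."""
    out: list[Breakpoint] = []
    for seg in segments:
        if seg.state not in states:
            continue
        block = probes.chrom_block(seg.interval.chrom)
        if block.empty:
            raise ValueError(f"segment {seg.interval} references chromosome with no probes")
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        inside = (starts >= seg.interval.start) & (ends <= seg.interval.end)
        idx = inside.nonzero()[0]
        if len(idx) == 0:
            raise ValueError(f"segment {seg.interval} contains no probes from the probe set")
        first, last = int(idx[0]), int(idx[-1])
        if first > 0:
            out.append(
                Breakpoint(
                    sample=seg.sample,
                    interval=GenomicInterval(
                        seg.interval.chrom,
                        int(min(starts[first - 1], starts[first])),
                        int(max(ends[first - 1], ends[first])),
                    ),
                    side="left",
                    segment=seg,
                )
            )
        if last < len(block) - 1:
            out.append(
                Breakpoint(
                    sample=seg.sample,
                    interval=GenomicInterval(
                        seg.interval.chrom,
                        int(min(starts[last], starts[last + 1])),
                        int(max(ends[last], ends[last + 1])),
                    ),
                    side="right",
                    segment=seg,
                )
            )
    return out


def count_breakpoints(breakpoints: list[Breakpoint], sample: str) -> int:
    return sum(1 for b in breakpoints if b.sample == sample)


def _merge_sample_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_cbps(
    breakpoints: list[Breakpoint],
    cohort_size: int,
    min_support: int = 4,
    merge_gap: int = 0,
) -> list[CBP]:
    """Sweep-line recurrence calling over breakpoint intervals.

    A sample counts once per position regardless of how many of its
    breakpoints overlap there; maximal regions with distinct-sample coverage
    >= ``min_support`` become CBPs, and qualifying regions separated by at
    most ``merge_gap`` bp are merged.  ``break_frequency`` is
    100 x supporting samples / cohort size.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for b in breakpoints:
        by_chrom.setdefault(b.interval.chrom, {}).setdefault(b.sample, []).append(
            (b.interval.start, b.interval.end)
        )
    cbps: list[CBP] = []
    for chrom in sorted(by_chrom):
        events: list[tuple[int, int]] = []  # (position, +1/-1)
        sample_ivs: dict[str, list[tuple[int, int]]] = {}
        for sample, ivs in by_chrom[chrom].items():
            merged = _merge_sample_intervals(ivs)
            sample_ivs[sample] = merged
            for s, e in merged:
                events.append((s, 1))
                events.append((e, -1))
        events.sort()
        # scan for maximal runs with coverage >= min_support
        regions: list[list[int]] = []
        cov = 0
        open_start: int | None = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                cov += events[i][1]
                i += 1
            if cov >= min_support and open_start is None:
                open_start = pos
            elif cov < min_support and open_start is not None:
                regions.append([open_start, pos])
                open_start = None
        merged_regions: list[list[int]] = []
        for s, e in regions:
            if merged_regions and s - merged_regions[-1][1] <= merge_gap:
                merged_regions[-1][1] = e
            else:
                merged_regions.append([s, e])
        for s, e in merged_regions:
            support = 0
            fp_lo, fp_hi = s, e
            for ivs in sample_ivs.values():
                hit = [(a, b) for a, b in ivs if a < e and b > s]
                if hit:
                    support += 1
                    fp_lo = min(fp_lo, min(a for a, _ in hit))
                    fp_hi = max(fp_hi, max(b for _, b in hit))
            cbps.append(
                CBP(
                    interval=GenomicInterval(chrom, s, e),
                    supporting_samples=support,
                    break_frequency=100.0 * support / cohort_size,
                    footprint=GenomicInterval(chrom, fp_lo, fp_hi),
                )
            )
    return cbps


def cbps_to_frame(cbps: list[CBP]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "footprint_start": c.density_interval.start,
                "footprint_end": c.density_interval.end,
                "support": c.supporting_samples,
                "break_frequency": c.break_frequency,
                "line1_density": c.repeat_density,
            }
            for c in cbps
        ],
        columns=["chrom", "start", "end", "footprint_start", "footprint_end",
                 "support", "break_frequency", "line1_density"],
    )
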