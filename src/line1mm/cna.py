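"""Copy-number calling from probe-level aCGH log2 ratios.

The caller is a deliberately simple run-threshold scan: maximal runs of
consecutive same-chromosome probes whose ratios all exceed ``+t`` (gain) or
fall below ``-t`` (loss) become candidate segments, and candidates are kept
when they contain at least ``min_probes`` probes and their mean |log2 ratio|
reaches ``min_abs_log2``.  Sex chromosomes can be excluded, reflecting their
distinct epigenetic regulation.  Pre-computed SEG-style segment tables may be
supplied instead of re-calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ArmMap, GenomeManifest, GenomicInterval, assign_arm

__all__ = [
    "ProbeSet",
    "SegmentCall",
    "ArmAberration",
    "call_segments",
    "call_arm_aberrations",
    "aberration_burden",
    "read_seg",
    "write_seg",
]

logger = logging.getLogger(__name__)

META_COLS = ["probe", "chrom", "start", "end"]


class ProbeSet:
    """Sorted probe-level log2-ratio matrix (probe interval x sample)."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns {missing}")
        if df["probe"].duplicated().any():
            raise ValueError("probe ids are not unique")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLS]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def __len__(self) -> int:
        return len(self.df)

    def chrom_block(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def probe_interval(self, row) -> GenomicInterval:
        return GenomicInterval(row.chrom, int(row.start), int(row.end))

    @classmethod
    def from_tsv(cls, path) -> "ProbeSet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SegmentCall:
    """One gain/loss run of probes for one sample."""

    sample: str
    interval: GenomicInterval
    state: str  # "loss" | "gain"
    probe_count: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.state not in ("loss", "gain"):
            raise ValueError(f"state must be loss|gain, got {self.state!r}")
        if self.state == "loss" and self.mean_log2 >= 0:
            raise ValueError("loss segment with non-negative mean log2")
        if self.state == "gain" and self.mean_log2 <= 0:
            raise ValueError("gain segment with non-positive mean log2")


@dataclass(frozen=True)
class ArmAberration:
    sample: str
    chrom: str
    arm: str
    state: str
    probes_in_state: int

    @property
    def arm_label(self) -> str:
        return f"{self.chrom.removeprefix('chr')}{self.arm}"


def call_segments(
    probes: ProbeSet,
    sample: str,
    min_probes: int = 3,
    min_abs_log2: float = 0.5,
    probe_threshold: float = 0.2,
    manifest: GenomeManifest | None = None,
    exclude_sex: bool = True,
) -> list[SegmentCall]:
    """Call gain/loss segments for one sample.

    Probes with missing ratios are dropped (with a logged count) and
    terminate any run in progress, so a segment is always a run of observed,
    consecutive probes.
    """
    if sample not in probes.samples:
        raise KeyError(f"sample {sample!r} not in probe table")
    calls: list[SegmentCall] = []
    n_missing = 0
    for chrom in probes.chroms:
        if exclude_sex and manifest is not None and manifest.is_sex(chrom):
            continue
        block = probes.chrom_block(chrom)
        ratio = block[sample].to_numpy(dtype=float)
        start = block["start"].to_numpy(dtype=int)
        end = block["end"].to_numpy(dtype=int)
        n_missing += int(np.isnan(ratio).sum())
        # sign of the candidate state per probe; 0 breaks every run
        sign = np.zeros(len(ratio), dtype=int)
        with np.errstate(invalid="ignore"):
            sign[ratio > probe_threshold] = 1
            sign[ratio < -probe_threshold] = -1
        i = 0
        n = len(sign)
        while i < n:
            s = sign[i]
            if s == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and sign[j + 1] == s:
                j += 1
            count = j - i + 1
            mean = float(ratio[i : j + 1].mean())
            if count >= min_probes and abs(mean) >= min_abs_log2:
                calls.append(
                    SegmentCall(
                        sample=sample,
                        interval=GenomicInterval(chrom, int(start[i]), int(end[j])),
                        state="loss" if s < 0 else "gain",
                        probe_count=count,
                        mean_log2=mean,
                    )
                )
            i = j + 1
    if n_missing:
        logger.warning("call_segments(%s): skipped %d probes with missing ratios", sample, n_missing)
    return calls


def _probes_in_segment(probes: ProbeSet, seg: SegmentCall) -> pd.DataFrame:
    block = probes.chrom_block(seg.interval.chrom)
    mid = (block["start"] + block["end"]) // 2
    return block[(mid >= seg.interval.start) & (mid < seg.interval.end)]


def call_arm_aberrations(
    segments: list[SegmentCall],
    probes: ProbeSet,
    arms: ArmMap,
    arm_min_probes: int = 50,
) -> list[ArmAberration]:
    """Arm-level gains/losses: strictly more than ``arm_min_probes`` probes
    inside same-state segments on one chromosome arm."""
    counts: dict[tuple[str, str, str, str], int] = {}
    for seg in segments:
        inside = _probes_in_segment(probes, seg)
        for row in inside.itertuples():
            arm = assign_arm(probes.probe_interval(row), arms)
            key = (seg.sample, seg.interval.chrom, arm, seg.state)
            counts[key] = counts.get(key, 0) + 1
    out = [
        ArmAberration(sample, chrom, arm, state, n)
        for (sample, chrom, arm, state), n in sorted(counts.items())
        if n > arm_min_probes
    ]
    return out


def aberration_burden(segments: list[SegmentCall], probes: ProbeSet) -> pd.DataFrame:
    """Per-sample counts of distinct probes covered by loss/gain segments.

    Returns a DataFrame indexed by sample with columns ``loss_probe_count``
    and ``gain_probe_count``; every sample appearing in ``segments`` or in
    the probe table is present (zero-filled).
    """
    seen: dict[str, dict[str, set]] = {}
    for seg in segments:
        inside = _probes_in_segment(probes, seg)
        bucket = seen.setdefault(seg.sample, {"loss": set(), "gain": set()})
        bucket[seg.state].update(inside["probe"])
    samples = sorted(set(probes.samples) | set(seen))
    return pd.DataFrame(
        {
            "loss_probe_count": [len(seen.get(s, {}).get("loss", ())) for s in samples],
            "gain_probe_count": [len(seen.get(s, {}).get("gain", ())) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )


SEG_COLS = ["sample", "chrom", "start", "end", "n_probes", "mean_log2"]


def read_seg(path) -> list[SegmentCall]:
    """Read a SEG-like tab-delimited segment table; state follows the sign of mean_log2."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns {missing}")
    return [
        SegmentCall(
            sample=str(r.sample),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            state="loss" if r.mean_log2 < 0 else "gain",
            probe_count=int(r.n_probes),
            mean_log2=float(r.mean_log2),
        )
        for r in df.itertuples()
    ]


def write_seg(segments: list[SegmentCall], path) -> None:
    pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "n_probes": s.probe_count,
                "mean_log2": s.mean_log2,
            }
            for s in segments
        ],
        columns=SEG_COLS,
    ).to_csv(path, sep="\t", index=False)
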