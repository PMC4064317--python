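"""MBD-seq methylation quantification over inter-probe windows.

The pipeline mirrors the enrichment-sequencing normalization cascade:
read counts in each window between sequential aCGH probes are divided by the
window length (reads per nucleotide), normalized to the matched input
(non-enriched) library, corrected for locus copy number from the aCGH calls,
then log-transformed and z-standardized per sample.  Windows whose input
count falls below one read are flagged and excluded from standardization,
and a pseudo-rate of half a read per window keeps the log transform defined.

Windows are carried as a pandas DataFrame with one row per window; each
operation adds columns and returns the frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cna import ProbeSet, SegmentCall
from .genome import GenomicInterval
from .repeats import DensityBinning, RepeatTrack, categorize, density

__all__ = [
    "build_windows",
    "quantify",
    "cn_normalize",
    "log_standardize",
    "region_mean",
    "add_window_density",
    "density_stratified_mean",
    "read_bed_intervals",
]


def read_bed_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def build_windows(probes: ProbeSet) -> pd.DataFrame:
    """One window per adjacent same-chromosome probe pair (end of the first
    probe to start of the next); overlapping/abutting pairs are skipped."""
    rows = []
    for chrom in probes.chroms:
        block = probes.chrom_block(chrom)
        ends = block["end"].to_numpy()
        starts = block["start"].to_numpy()
        for left_end, right_start in zip(ends[:-1], starts[1:]):
            if right_start <= left_end:
                continue
            rows.append((chrom, int(left_end), int(right_start)))
    win = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    win["length"] = win["end"] - win["start"]
    return win


def _midpoint_counts(windows: pd.DataFrame, reads: pd.DataFrame) -> np.ndarray:
    """Count reads whose midpoint falls inside each window (at most one window per read)."""
    counts = np.zeros(len(windows), dtype=int)
    widx = windows.reset_index(drop=True)
    for chrom, wgrp in widx.groupby("chrom", sort=False):
        rgrp = reads[reads["chrom"] == chrom]
        if rgrp.empty:
            continue
        mids = ((rgrp["start"] + rgrp["end"]) // 2).to_numpy()
        starts = wgrp["start"].to_numpy()
        ends = wgrp["end"].to_numpy()
        pos = np.searchsorted(starts, mids, side="right") - 1
        ok = (pos >= 0) & (mids < ends[np.clip(pos, 0, len(ends) - 1)])
        np.add.at(counts, wgrp.index.to_numpy()[pos[ok]], 1)
    return counts


def quantify(
    windows: pd.DataFrame,
    sample_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    pseudo_reads: float = 0.5,
    min_input_reads: int = 1,
) -> pd.DataFrame:
    """Fill read counts, per-nucleotide rates and the input-normalized level.

    ``level = (sample_rate + eps) / (input_rate + eps)`` with
    ``eps = pseudo_reads / length``; windows with fewer than
    ``min_input_reads`` input reads are flagged ``excluded``.
    """
    if len(sample_reads) == 0 and len(input_reads) == 0:
        raise ValueError("no reads supplied")
    out = windows.copy()
    out["sample_count"] = _midpoint_counts(out, sample_reads)
    out["input_count"] = _midpoint_counts(out, input_reads)
    length = out["length"].to_numpy(dtype=float)
    eps = pseudo_reads / length
    out["sample_rate"] = out["sample_count"] / length
    out["input_rate"] = out["input_count"] / length
    out["level"] = (out["sample_rate"] + eps) / (out["input_rate"] + eps)
    out["excluded"] = out["input_count"] < min_input_reads
    return out


def cn_normalize(
    windows: pd.DataFrame,
    segments: list[SegmentCall],
    continuous: bool = False,
) -> pd.DataFrame:
    """Divide levels by CN/2, with CN 1 in loss segments, 3 in gains, 2 elsewhere
    (or ``2 * 2**mean_log2`` of the containing segment when ``continuous``)."""
    out = windows.copy()
    mid = ((out["start"] + out["end"]) // 2).to_numpy()
    cn = np.full(len(out), 2.0)
    for seg in segments:
        hit = (
            (out["chrom"].to_numpy() == seg.interval.chrom)
            & (mid >= seg.interval.start)
            & (mid < seg.interval.end)
        )
        if continuous:
            cn[hit] = 2.0 * 2.0 ** seg.mean_log2
        else:
            cn[hit] = 1.0 if seg.state == "loss" else 3.0
    out["copy_number"] = cn
    out["level"] = out["level"] / (cn / 2.0)
    return out


def log_standardize(windows: pd.DataFrame) -> pd.DataFrame:
    """Per-sample z-standardization of log levels over non-excluded windows."""
    out = windows.copy()
    keep = ~out["excluded"].to_numpy() if "excluded" in out.columns else np.ones(len(out), bool)
    logs = np.log(out.loc[keep, "level"].to_numpy(dtype=float))
    sd = logs.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("log levels have zero variance; standardization undefined")
    out["z"] = np.nan
    out.loc[keep, "z"] = (logs - logs.mean()) / sd
    return out


def _midpoint_in_regions(windows: pd.DataFrame, regions) -> np.ndarray:
    if isinstance(regions, pd.DataFrame):
        regions = [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in regions.itertuples()
        ]
    else:
        regions = [r.interval if hasattr(r, "interval") else r for r in regions]
    mid = ((windows["start"] + windows["end"]) // 2).to_numpy()
    chroms = windows["chrom"].to_numpy()
    mask = np.zeros(len(windows), dtype=bool)
    for iv in regions:
        mask |= (chroms == iv.chrom) & (mid >= iv.start) & (mid < iv.end)
    return mask


def region_mean(windows: pd.DataFrame, regions) -> float:
    """Mean z over windows whose midpoint lies in any region (NaN when none do).

    The whole-genome mean is 0 by construction of the standardization, so
    this is directly the deviation of the region set from the genome.
    """
    mask = _midpoint_in_regions(windows, regions)
    z = windows.loc[mask, "z"].dropna()
    return float(z.mean()) if len(z) else float("nan")


def add_window_density(
    windows: pd.DataFrame, track: RepeatTrack, family: str = "LINE-1"
) -> pd.DataFrame:
    out = windows.copy()
    out["density"] = [
        density(GenomicInterval(str(r.chrom), int(r.start), int(r.end)), track, family)
        for r in out.itertuples()
    ]
    return out


def density_stratified_mean(
    windows: pd.DataFrame, binning: DensityBinning
) -> tuple[pd.DataFrame, float]:
    """Mean z per repeat-density category and the Pearson correlation of z
    with the ordinal category (empty categories reported as NaN, excluded
    from the correlation)."""
    if "density" not in windows.columns:
        raise ValueError("windows lack a density column; call add_window_density first")
    cat = windows["density"].map(lambda v: categorize(v, binning))
    ok = windows["z"].notna()
    per_cat = (
        pd.DataFrame({"category": cat[ok], "z": windows.loc[ok, "z"]})
        .groupby("category")["z"]
        .agg(["mean", "count"])
        .reindex(range(1, 6))
    )
    sub = windows.loc[ok]
    r = float(np.corrcoef(cat[ok].to_numpy(dtype=float), sub["z"].to_numpy())[0, 1])
    return per_cat, r
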