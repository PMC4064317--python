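"""Synthetic myeloma cohort generator.

Produces a complete toy cohort with the statistical structure the analysis
stages are built to detect, so every stage can be exercised end-to-end
without external data:

* a toy genome (a few autosomes of tens of Mb plus a flagged sex
  chromosome) tiled with LINE-1 and Alu annotation records whose per-window
  density spans the five-category range;
* evenly spaced aCGH probes with per-sample log2 ratios = true segment mean
  + Gaussian probe noise, so the run-threshold caller is exercised
  nontrivially;
* per-sample copy-number-loss segments whose boundaries fall in probe gaps
  drawn with probability proportional to ``exp(beta * (density category - 1))``
  of the containing window — the planted breakpoint/LINE-1-density link;
* global methylation levels inversely tied to loss burden:
  ``LINE-1 % = alpha - gamma * log10(loss probes + 1) + noise``, with the
  other elements noisy affine transforms of LINE-1;
* MBD-seq-like read sets: window read counts Poisson with mean proportional
  to depth x (methylation/100) x (copy number/2) for the enriched channel
  and to depth for the input channel;
* survival times, exponential with the hazard multiplied by the configured
  hazard ratio for samples below the cohort median methylation, under
  independent exponential censoring.

The hypomethylated group for survival simulation is defined by the cohort
median, not the ROC cutoff, keeping the ground truth independent of the
estimator under test.  A fixed seed makes the output bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cna import ProbeSet, SegmentCall, read_seg, write_seg
from .genome import GenomeManifest, GenomicInterval
from .repeats import RepeatTrack, derive_binning, categorize
from . import mbd as mbd_mod

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_toy_genome",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "sample_breakpoint_categories",
    "simulate_burden_methylation",
    "simulate_survival_cohort",
    "simulate_mbd_reads",
]


def default_toy_genome() -> GenomeManifest:
    """Three autosomes (20/15/10 Mb) plus a 5 Mb flagged sex chromosome."""
    return GenomeManifest(
        {"chr1": 20_000_000, "chr2": 15_000_000, "chr3": 10_000_000, "chrX": 5_000_000},
        sex_chroms=frozenset({"chrX"}),
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 67
    genome: GenomeManifest = field(default_factory=default_toy_genome)
    probe_spacing: int = 50_000
    probe_length: int = 60
    window_size: int = 100_000
    # repeat landscape (per full window)
    line1_mean_per_window: float = 25.0
    line1_zero_window_frac: float = 0.08
    line1_gamma_shape: float = 2.0
    alu_mean_per_window: float = 10.0
    repeat_density_profile: np.ndarray | None = None  # explicit per-window means override
    # copy-number process
    breakpoint_enrichment_beta: float = 0.4
    loss_rate: float = 6.0
    gain_rate: float = 2.0
    seg_min_probes: int = 4
    seg_max_probes: int = 30
    loss_log2: float = -0.8
    gain_log2: float = 0.7
    probe_noise_sd: float = 0.15
    # methylation link
    meth_intercept: float = 48.0  # alpha, %
    meth_slope: float = 6.0  # gamma, % per log10(loss probes + 1)
    meth_noise_sd: float = 5.0  # %
    # MBD-seq
    mbd_depth: float = 3.0  # mean input reads per window
    n_mbd_samples: int | None = None  # default min(n_samples, 9)
    density_meth_slope: float = 0.0  # per-category log effect on window methylation
    read_length: int = 50
    # survival
    hazard_ratio: float = 2.8
    baseline_hazard: float = np.log(2) / 1500.0  # per day; median OS ~ 4 years
    censor_hazard: float = np.log(2) / 1500.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("loss_rate", "gain_rate", "probe_noise_sd", "meth_noise_sd",
                     "mbd_depth", "baseline_hazard", "censor_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    probes: ProbeSet
    true_segments: list[SegmentCall]
    repeats: RepeatTrack
    windows: pd.DataFrame  # genome windows with density + category
    profiles: pd.DataFrame  # per-sample element methylation (%)
    clinical: pd.DataFrame
    sample_reads: dict[str, pd.DataFrame]
    input_reads: pd.DataFrame
    truth: dict


def _sample_ids(n: int) -> list[str]:
    return [f"MM{i + 1:03d}" for i in range(n)]


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome
    autosomes = genome.autosomes()
    if not autosomes:
        raise ValueError("genome has no autosomes")

    # ---- repeat landscape and density windows -------------------------------
    win_rows = []
    for chrom in autosomes:
        length = genome.lengths[chrom]
        for start in range(0, length, cfg.window_size):
            win_rows.append((chrom, start, min(start + cfg.window_size, length)))
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end"])
    n_win = len(windows)
    if cfg.repeat_density_profile is not None:
        means = np.asarray(cfg.repeat_density_profile, dtype=float)
        if len(means) != n_win:
            raise ValueError(f"repeat_density_profile length {len(means)} != {n_win} windows")
    else:
        means = rng.gamma(cfg.line1_gamma_shape,
                          cfg.line1_mean_per_window / cfg.line1_gamma_shape, size=n_win)
        means[rng.random(n_win) < cfg.line1_zero_window_frac] = 0.0
    line1_counts = rng.poisson(means)
    alu_counts = rng.poisson(cfg.alu_mean_per_window, size=n_win)

    rep_rows = []
    for (w, l1, alu) in zip(windows.itertuples(), line1_counts, alu_counts):
        for fam, count, lmin, lmax in (("LINE-1", l1, 300, 3000), ("Alu", alu, 100, 350)):
            if count == 0:
                continue
            starts = rng.integers(w.start, w.end - 1, size=count)
            lens = rng.integers(lmin, lmax, size=count)
            ends = np.minimum(starts + lens, w.end)
            for s, e in zip(starts, ends):
                rep_rows.append((w.chrom, int(s), int(e), fam))
    repeats = RepeatTrack(pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "family"]))

    lengths = (windows["end"] - windows["start"]).to_numpy()
    windows["density"] = line1_counts / lengths * 100_000
    binning = derive_binning(windows["density"])
    windows["category"] = windows["density"].map(lambda v: categorize(v, binning))

    # ---- probes -------------------------------------------------------------
    probe_rows = []
    for chrom in genome.chroms:
        length = genome.lengths[chrom]
        pos = cfg.probe_spacing // 2
        i = 0
        while pos + cfg.probe_length < length:
            probe_rows.append((f"{chrom}_p{i:05d}", chrom, pos, pos + cfg.probe_length))
            pos += cfg.probe_spacing
            i += 1
    probe_df = pd.DataFrame(probe_rows, columns=["probe", "chrom", "start", "end"])
    samples = _sample_ids(cfg.n_samples)

    # per-chromosome probe coordinates and gap weights on autosomes
    chrom_probes = {c: probe_df[probe_df["chrom"] == c].reset_index(drop=True) for c in autosomes}
    for c in autosomes:
        if len(chrom_probes[c]) < cfg.seg_min_probes + 2:
            raise ValueError(f"chromosome {c} carries too few probes to place segments")
    win_by_chrom = {c: windows[windows["chrom"] == c].reset_index(drop=True) for c in autosomes}
    gap_weights: dict[str, np.ndarray] = {}
    gap_cats: dict[str, np.ndarray] = {}
    for c in autosomes:
        blk = chrom_probes[c]
        mids = ((blk["end"].to_numpy()[:-1] + blk["start"].to_numpy()[1:]) // 2)
        wblk = win_by_chrom[c]
        idx = np.clip(np.searchsorted(wblk["start"].to_numpy(), mids, side="right") - 1, 0, len(wblk) - 1)
        cats = wblk["category"].to_numpy()[idx]
        gap_cats[c] = cats
        gap_weights[c] = np.exp(cfg.breakpoint_enrichment_beta * (cats - 1))
    chrom_total_w = np.array([gap_weights[c].sum() for c in autosomes], dtype=float)
    chrom_p = chrom_total_w / chrom_total_w.sum()

    # ---- per-sample segments ------------------------------------------------
    true_segments: list[SegmentCall] = []
    truth_bp: dict[str, list[dict]] = {s: [] for s in samples}
    for s in samples:
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in autosomes}

        def place(state: str, enriched: bool, sample=s, occupied=occupied) -> SegmentCall | None:
            for _ in range(60):
                chrom = autosomes[rng.choice(len(autosomes), p=chrom_p)]
                w = gap_weights[chrom] if enriched else np.ones_like(gap_weights[chrom])
                p = w / w.sum()
                g1 = int(rng.choice(len(p), p=p))
                g2 = int(rng.choice(len(p), p=p))
                if g1 > g2:
                    g1, g2 = g2, g1
                n_probes = g2 - g1
                if not (cfg.seg_min_probes <= n_probes <= cfg.seg_max_probes):
                    continue
                if any(g1 < e and g2 > a for a, e in occupied[chrom]):
                    continue
                occupied[chrom].append((g1, g2))
                blk = chrom_probes[chrom]
                mean = cfg.loss_log2 if state == "loss" else cfg.gain_log2
                seg = SegmentCall(
                    sample=sample,
                    interval=GenomicInterval(
                        chrom, int(blk["start"].iloc[g1 + 1]), int(blk["end"].iloc[g2])
                    ),
                    state=state,
                    probe_count=n_probes,
                    mean_log2=mean,
                )
                if state == "loss":
                    truth_bp[sample].extend(
                        {"chrom": chrom, "gap": g, "category": int(gap_cats[chrom][g])}
                        for g in (g1, g2)
                    )
                return seg
            return None

        for _ in range(rng.poisson(cfg.loss_rate)):
            seg = place("loss", enriched=True)
            if seg:
                true_segments.append(seg)
        for _ in range(rng.poisson(cfg.gain_rate)):
            seg = place("gain", enriched=False)
            if seg:
                true_segments.append(seg)

    # ---- probe log2 matrix --------------------------------------------------
    ratios = rng.normal(0.0, cfg.probe_noise_sd, size=(len(probe_df), cfg.n_samples))
    col_of = {s: j for j, s in enumerate(samples)}
    starts_all = probe_df["start"].to_numpy()
    ends_all = probe_df["end"].to_numpy()
    chrom_all = probe_df["chrom"].to_numpy()
    for seg in true_segments:
        hit = (
            (chrom_all == seg.interval.chrom)
            & (starts_all >= seg.interval.start)
            & (ends_all <= seg.interval.end)
        )
        ratios[hit, col_of[seg.sample]] += seg.mean_log2
    matrix = probe_df.copy()
    for j, s in enumerate(samples):
        matrix[s] = ratios[:, j]
    probes = ProbeSet(matrix)

    # ---- methylation profiles ----------------------------------------------
    loss_burden = np.zeros(cfg.n_samples)
    for seg in true_segments:
        if seg.state == "loss":
            loss_burden[samples.index(seg.sample)] += seg.probe_count
    log_burden = np.log10(loss_burden + 1.0)
    line1 = cfg.meth_intercept - cfg.meth_slope * log_burden + rng.normal(
        0.0, cfg.meth_noise_sd, cfg.n_samples
    )
    line1 = np.clip(line1, 0.0, 100.0)
    profiles = pd.DataFrame(
        {
            "line1": line1,
            "alu_ya5": np.clip(0.6 * line1 + 8.0 + rng.normal(0, 2.5, cfg.n_samples), 0, 100),
            "alu_yb8": np.clip(0.5 * line1 + 15.0 + rng.normal(0, 2.5, cfg.n_samples), 0, 100),
            "sat_alpha": np.clip(0.7 * line1 - 5.0 + rng.normal(0, 4.0, cfg.n_samples), 0, 100),
        },
        index=pd.Index(samples, name="sample"),
    )

    # ---- MBD-seq reads ------------------------------------------------------
    mbd_windows = mbd_mod.build_windows(probes)
    mbd_windows = mbd_windows[mbd_windows["chrom"].isin(autosomes)].reset_index(drop=True)
    wmid = ((mbd_windows["start"] + mbd_windows["end"]) // 2).to_numpy()
    wcat = np.empty(len(mbd_windows), dtype=int)
    for c in autosomes:
        m = mbd_windows["chrom"].to_numpy() == c
        wblk = win_by_chrom[c]
        idx = np.clip(
            np.searchsorted(wblk["start"].to_numpy(), wmid[m], side="right") - 1, 0, len(wblk) - 1
        )
        wcat[m] = wblk["category"].to_numpy()[idx]
    n_mbd = cfg.n_mbd_samples if cfg.n_mbd_samples is not None else min(cfg.n_samples, 9)
    sample_reads: dict[str, pd.DataFrame] = {}
    cat_effect = np.exp(cfg.density_meth_slope * (wcat - 3))
    for s in samples[:n_mbd]:
        cn = np.full(len(mbd_windows), 2.0)
        for seg in true_segments:
            if seg.sample != s:
                continue
            hit = (
                (mbd_windows["chrom"].to_numpy() == seg.interval.chrom)
                & (wmid >= seg.interval.start)
                & (wmid < seg.interval.end)
            )
            cn[hit] = 1.0 if seg.state == "loss" else 3.0
        meth_w = np.clip(profiles.loc[s, "line1"] * cat_effect, 0.0, 100.0)
        sample_reads[s], _ = simulate_mbd_reads(
            rng, mbd_windows, cfg.mbd_depth, meth_w, cn=cn,
            read_length=cfg.read_length, with_input=False,
        )
    _, input_reads = simulate_mbd_reads(
        rng, mbd_windows, cfg.mbd_depth, 100.0, read_length=cfg.read_length, with_sample=False
    )

    # ---- clinical -----------------------------------------------------------
    hypo = (line1 < np.median(line1)).astype(int)
    hazard = cfg.baseline_hazard * np.where(hypo == 1, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / cfg.censor_hazard, cfg.n_samples)
        if cfg.censor_hazard > 0
        else np.full(cfg.n_samples, np.inf)
    )
    os_days = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    meth_rank = pd.Series(line1).rank(pct=True).to_numpy()
    stage_p3 = np.clip(0.8 - 0.6 * meth_rank, 0.05, 0.95)  # lower methylation -> higher stage
    u = rng.random(cfg.n_samples)
    iss = np.where(u < stage_p3, 3, np.where(u < stage_p3 + 0.3, 2, 1))
    has_chr1_loss = np.zeros(cfg.n_samples, dtype=int)
    for seg in true_segments:
        if seg.state == "loss" and seg.interval.chrom == autosomes[0]:
            has_chr1_loss[samples.index(seg.sample)] = 1
    clinical = pd.DataFrame(
        {
            "age": np.clip(rng.normal(65, 8, cfg.n_samples).round(), 35, 90).astype(int),
            "sex_male": rng.integers(0, 2, cfg.n_samples),
            "iss_stage": iss,
            "center": rng.choice(["A", "B"], cfg.n_samples),
            "chr13_loss": has_chr1_loss,
            "os_days": np.round(os_days, 1),
            "os_diagnosis_days": np.round(os_days + rng.uniform(0, 600, cfg.n_samples), 1),
            "event": event,
        },
        index=pd.Index(samples, name="sample"),
    )

    truth = {
        "binning_edges": list(binning.edges),
        "genome_category_counts": [int((windows["category"] == k).sum()) for k in range(1, 6)],
        "loss_burden": {s: int(b) for s, b in zip(samples, loss_burden)},
        "breakpoints": truth_bp,
        "n_true_breakpoints": {s: len(v) for s, v in truth_bp.items()},
        "hypomethylated": {s: int(h) for s, h in zip(samples, hypo)},
        "hazard_ratio": cfg.hazard_ratio,
        "n_loss_segments": sum(1 for g in true_segments if g.state == "loss"),
        "n_gain_segments": sum(1 for g in true_segments if g.state == "gain"),
    }
    return SyntheticCohort(
        config=cfg,
        probes=probes,
        true_segments=true_segments,
        repeats=repeats,
        windows=windows,
        profiles=profiles,
        clinical=clinical,
        sample_reads=sample_reads,
        input_reads=input_reads,
        truth=truth,
    )


def simulate_mbd_reads(
    rng: np.random.Generator,
    windows: pd.DataFrame,
    depth: float,
    meth_percent,
    cn=None,
    region_mask=None,
    region_scale: float = 1.0,
    read_length: int = 50,
    with_sample: bool = True,
    with_input: bool = True,
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Poisson read sets over windows for the enriched and input channels.

    Enriched-channel mean per window: ``depth * (meth/100) * (cn/2)``,
    optionally multiplied by ``region_scale`` inside ``region_mask`` (to
    plant regional hypo/hypermethylation); input-channel mean: ``depth``.
    """
    n = len(windows)
    meth = np.broadcast_to(np.asarray(meth_percent, dtype=float), (n,))
    cn = np.full(n, 2.0) if cn is None else np.asarray(cn, dtype=float)
    rate = depth * (meth / 100.0) * (cn / 2.0)
    if region_mask is not None:
        rate = np.where(np.asarray(region_mask, bool), rate * region_scale, rate)

    def _draw(lam) -> pd.DataFrame:
        counts = rng.poisson(lam)
        rows = []
        for w, k in zip(windows.itertuples(), counts):
            if k == 0:
                continue
            starts = rng.integers(w.start, max(w.start + 1, w.end - read_length), size=k)
            for s in np.sort(starts):
                rows.append((w.chrom, int(s), int(min(s + read_length, w.end))))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    sample_df = _draw(rate) if with_sample else None
    input_df = _draw(np.full(n, float(depth))) if with_input else None
    return sample_df, input_df


def sample_breakpoint_categories(
    rng: np.random.Generator, window_categories, beta: float, n_breakpoints: int
) -> np.ndarray:
    """Draw breakpoint host-window categories with log-odds increment ``beta``
    per density category (the generator's placement rule, standalone)."""
    cats = np.asarray(window_categories, dtype=int)
    w = np.exp(beta * (cats - 1))
    idx = rng.choice(len(cats), size=n_breakpoints, p=w / w.sum())
    return cats[idx]


def simulate_burden_methylation(
    rng: np.random.Generator,
    n: int,
    r: float = -0.5,
    meth_mean: float = 45.0,
    meth_sd: float = 7.0,
    log_burden_mean: float = 1.0,
    log_burden_sd: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Loss-probe counts and methylation with planted population correlation
    ``r`` between log10(count + 1) and methylation."""
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    counts = np.maximum(np.round(10 ** (log_burden_mean + log_burden_sd * z1) - 1), 0).astype(int)
    lb = (np.log10(counts + 1.0) - log_burden_mean) / log_burden_sd
    meth = meth_mean + meth_sd * (r * lb + np.sqrt(1 - r * r) * z2)
    return counts, meth


def simulate_survival_cohort(
    rng: np.random.Generator,
    n: int = 74,
    hazard_ratio: float = 2.8,
    baseline_hazard: float = np.log(2) / 1500.0,
    censor_hazard: float = np.log(2) / 1500.0,
) -> pd.DataFrame:
    """Two equal groups with exponential survival, hazard multiplied by
    ``hazard_ratio`` in the hypomethylated group, exponential censoring."""
    group = np.zeros(n, dtype=int)
    group[: n // 2] = 1
    hazard = baseline_hazard * np.where(group == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / censor_hazard, n) if censor_hazard > 0 else np.full(n, np.inf)
    return pd.DataFrame(
        {
            "hypomethylated": group,
            "os_days": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )


# ---- cohort I/O -------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Emit the cohort as plain-text files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": str(out / "probes.tsv"),
        "segments": str(out / "segments.seg"),
        "repeats": str(out / "repeats.bed"),
        "manifest": str(out / "genome.tsv"),
        "profiles": str(out / "profiles.csv"),
        "clinical": str(out / "clinical.csv"),
        "input_reads": str(out / "reads_input.bed"),
        "truth": str(out / "ground_truth.json"),
    }
    cohort.probes.to_tsv(paths["probes"])
    write_seg(cohort.true_segments, paths["segments"])
    cohort.repeats.to_bed(paths["repeats"])
    cohort.config.genome.to_table(paths["manifest"])
    cohort.profiles.reset_index().to_csv(paths["profiles"], index=False)
    cohort.clinical.reset_index().to_csv(paths["clinical"], index=False)
    cohort.input_reads.to_csv(paths["input_reads"], sep="\t", header=False, index=False)
    for s, reads in cohort.sample_reads.items():
        p = out / f"reads_{s}.bed"
        reads.to_csv(p, sep="\t", header=False, index=False)
        paths[f"reads_{s}"] = str(p)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return paths


def read_cohort(outdir) -> dict:
    """Read an emitted cohort back through the package readers."""
    from .survival import read_clinical

    out = Path(outdir)
    parts = {
        "probes": ProbeSet.from_tsv(out / "probes.tsv"),
        "segments": read_seg(out / "segments.seg"),
        "repeats": RepeatTrack.from_bed(out / "repeats.bed"),
        "manifest": GenomeManifest.from_table(out / "genome.tsv"),
        "profiles": pd.read_csv(out / "profiles.csv").set_index("sample"),
        "clinical": read_clinical(out / "clinical.csv"),
        "input_reads": mbd_mod.read_bed_intervals(out / "reads_input.bed"),
        "sample_reads": {
            p.stem.removeprefix("reads_"): mbd_mod.read_bed_intervals(p)
            for p in sorted(out.glob("reads_MM*.bed"))
        },
    }
    with open(out / "ground_truth.json") as fh:
        parts["truth"] = json.load(fh)
    return parts
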