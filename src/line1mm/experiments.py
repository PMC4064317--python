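"""Reproduction experiments: the package's operating characteristics under
the study conditions it was built for.

Each function runs a self-contained simulation study (or summarizes the
packaged published table) and returns plain numbers: trend-test calibration
under null breakpoint placement, power to detect density enrichment at
common breakpoints, recovery of a planted burden-methylation correlation,
direction of planted regional hypomethylation in MBD quantification, and
confidence-interval coverage and log-rank power for the survival model.
Problem sizes default to the cohort scale of the original study (67 aCGH
samples, 80 recurrent breakpoints, 74 patients with follow-up).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cna import call_segments
from .breakpoints import extract_breakpoints, find_cbps
from .datasets import load_common_breakpoints
from .mbd import build_windows, cn_normalize, log_standardize, quantify, region_mean
from .repeats import categorize, cbp_density_enrichment, density, derive_binning, mh_linear_trend
from .simulate import (
    SimulationConfig,
    sample_breakpoint_categories,
    simulate_burden_methylation,
    simulate_cohort,
    simulate_mbd_reads,
    simulate_survival_cohort,
)
from .stats import corr_burden
from .survival import cox_fit, logrank

__all__ = [
    "published_cbp_summary",
    "trend_null_calibration",
    "enrichment_power",
    "correlation_recovery",
    "mbd_regional_hypomethylation",
    "survival_operating_characteristics",
]


def published_cbp_summary() -> dict:
    """Mean LINE-1 density and the recurrence floor of the packaged
    80-region common-breakpoint table."""
    df = load_common_breakpoints()
    cats = df["line1_density"].map(categorize)
    return {
        "n_cbps": int(len(df)),
        "mean_line1_density": float(df["line1_density"].mean()),
        "min_break_frequency": float(df["break_frequency"].min()),
        "category_counts": [int((cats == k).sum()) for k in range(1, 6)],
    }


def _genome_scale_categories(rng: np.random.Generator, n_windows: int = 20_000) -> np.ndarray:
    """Window density categories at genome-representative scale, drawn once
    from the generator's repeat model.

    The trend test compares a census row (all genome windows) against a
    sampled row (~80 breakpoints); its finite-sample calibration is governed
    by the census-to-sample ratio, so calibration is assessed at a
    background size representative of a full genome in 100 kb windows.
    """
    cfg = SimulationConfig()
    means = rng.gamma(
        cfg.line1_gamma_shape, cfg.line1_mean_per_window / cfg.line1_gamma_shape, size=n_windows
    )
    means[rng.random(n_windows) < cfg.line1_zero_window_frac] = 0.0
    dens = rng.poisson(means).astype(float)
    binning = derive_binning(dens)
    return np.array([categorize(v, binning) for v in dens])


def trend_null_calibration(
    seed: int, n_reps: int = 1000, n_breakpoints: int = 80, alpha: float = 0.05
) -> dict:
    """Rejection rate of the linear-trend test when breakpoints are placed
    uniformly (no density enrichment)."""
    rng = np.random.default_rng(seed)
    cats = _genome_scale_categories(rng)
    genome_row = np.bincount(cats, minlength=6)[1:6]
    rejections = 0
    for _ in range(n_reps):
        bp_cats = sample_breakpoint_categories(rng, cats, beta=0.0, n_breakpoints=n_breakpoints)
        bp_row = np.bincount(bp_cats, minlength=6)[1:6]
        _, p = mh_linear_trend(np.vstack([genome_row, bp_row]))
        rejections += p < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def simulate_and_find_cbps(seed: int, n_samples: int = 67):
    """Full pipeline on one simulated cohort: probe-level calling ->
    breakpoints -> CBPs with footprint densities; returns (report, n_cbps)."""
    cfg = SimulationConfig(seed=seed, n_samples=n_samples, n_mbd_samples=0)
    cohort = simulate_cohort(cfg)
    segments = []
    for s in cohort.probes.samples:
        segments.extend(call_segments(cohort.probes, s, manifest=cfg.genome))
    bps = extract_breakpoints(segments, cohort.probes)
    cbps = find_cbps(bps, n_samples, min_support=4)
    if not cbps:
        return None, 0
    binning = derive_binning(cohort.windows["density"])
    for c in cbps:
        c.repeat_density = density(c.density_interval, cohort.repeats)
    report = cbp_density_enrichment(cbps, cohort.windows["density"], binning)
    return report, len(cbps)


def enrichment_power(seed: int, n_cohorts: int = 100, alpha: float = 0.05) -> dict:
    """Fraction of simulated cohorts (default enrichment effect) in which the
    CBP-vs-genome density trend test rejects."""
    rng = np.random.default_rng(seed)
    rejections, n_cbps, cbp_means, genome_means = 0, [], [], []
    for _ in range(n_cohorts):
        rep, k = simulate_and_find_cbps(int(rng.integers(0, 2**31 - 1)))
        if rep is None:
            continue
        rejections += rep["trend_p"] < alpha
        n_cbps.append(k)
        cbp_means.append(rep["cbp_mean_density"])
        genome_means.append(rep["genome_mean_density"])
    return {
        "rejection_rate": rejections / n_cohorts,
        "mean_n_cbps": float(np.mean(n_cbps)),
        "mean_cbp_density": float(np.mean(cbp_means)),
        "mean_genome_density": float(np.mean(genome_means)),
        "n_cohorts": n_cohorts,
    }


def correlation_recovery(
    seed: int, n_reps: int = 200, n: int = 67, r_true: float = -0.5
) -> dict:
    """Mean Pearson estimate for a planted burden-methylation correlation."""
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        counts, meth = simulate_burden_methylation(rng, n=n, r=r_true)
        profiles = pd.DataFrame({"line1": meth})
        r, _, _ = corr_burden(profiles, pd.Series(counts.astype(float)))
        estimates.append(r)
    mean_r = float(np.mean(estimates))
    return {"mean_r": mean_r, "bias": mean_r - r_true, "r_true": r_true, "n_reps": n_reps}


def mbd_regional_hypomethylation(
    seed: int, n_samples: int = 6, region_scale: float = 0.6, depth: float = 5.0
) -> dict:
    """Planted low methylation at designated (CBP-like) windows: mean
    standardized methylation level over those windows, per sample."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(seed=seed, n_samples=2, n_mbd_samples=0)
    cohort = simulate_cohort(cfg)
    shells = build_windows(cohort.probes)
    shells = shells[shells["chrom"].isin(cfg.genome.autosomes())].reset_index(drop=True)
    n_win = len(shells)
    region_mask = np.zeros(n_win, dtype=bool)
    region_mask[rng.choice(n_win, size=max(10, n_win // 12), replace=False)] = True
    regions = shells.loc[region_mask]
    zs = []
    for _ in range(n_samples):
        reads, inp = simulate_mbd_reads(
            rng, shells, depth, 60.0, region_mask=region_mask, region_scale=region_scale
        )
        win = quantify(shells, reads, inp)
        win = cn_normalize(win, [])
        win = log_standardize(win)
        zs.append(region_mean(win, regions))
    return {"mean_z_at_regions": float(np.mean(zs)), "per_sample_z": zs}


def survival_operating_characteristics(
    seed: int, n_reps: int = 500, n: int = 74, hazard_ratio: float = 2.8, alpha: float = 0.05
) -> dict:
    """CI coverage of the true hazard ratio and log-rank power across
    simulated cohorts of the published follow-up size."""
    rng = np.random.default_rng(seed)
    covered, significant, hrs = 0, 0, []
    for _ in range(n_reps):
        df = simulate_survival_cohort(rng, n=n, hazard_ratio=hazard_ratio)
        fit = cox_fit(df, ["hypomethylated"])
        s = fit.summary.loc["hypomethylated"]
        covered += s["ci_low"] <= hazard_ratio <= s["ci_high"]
        hrs.append(s["hr"])
        groups = [
            (df.loc[df["hypomethylated"] == g, "os_days"], df.loc[df["hypomethylated"] == g, "event"])
            for g in (0, 1)
        ]
        _, p = logrank(groups)
        significant += p < alpha
    return {
        "ci_coverage": covered / n_reps,
        "logrank_power": significant / n_reps,
        "median_hr": float(np.median(hrs)),
        "hazard_ratio_true": hazard_ratio,
        "n_reps": n_reps,
    }
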