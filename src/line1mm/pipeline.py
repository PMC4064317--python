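"""End-to-end orchestration: simulate/load -> copy-number calling ->
breakpoints/CBPs -> repeat density -> MBD quantification -> association
statistics -> survival, from a single config.

Artifacts are written with a manifest of parameters and input checksums;
rerunning with an unchanged config and inputs reuses the completed run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna, mbd, stats
from .breakpoints import cbps_to_frame, extract_breakpoints, find_cbps
from .genome import ArmMap, GenomeManifest, GenomicInterval, load_cytobands
from .repeats import (
    PUBLISHED_BINNING,
    RepeatTrack,
    cbp_density_enrichment,
    density,
    derive_binning,
    genome_windows,
)
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .survival import read_clinical, survival_report

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or missing input data (CLI exit code 3)."""


class DegeneracyError(ValueError):
    """Statistically degenerate inputs, e.g. zero variance (CLI exit code 4)."""


@dataclass
class RunConfig:
    outdir: str = "line1mm_run"
    seed: int = 0
    simulate: dict | None = None  # SimulationConfig overrides; None -> use input paths
    probes: str | None = None
    segments: str | None = None  # pre-computed SEG table bypasses the caller
    repeats: str | None = None
    manifest: str | None = None
    cytobands: str | None = None
    clinical: str | None = None
    profiles: str | None = None
    sample_reads: dict[str, str] = field(default_factory=dict)
    input_reads: str | None = None
    # stage parameters
    min_probes: int = 3
    min_abs_log2: float = 0.5
    probe_threshold: float = 0.2
    exclude_sex: bool = True
    arm_min_probes: int = 50
    min_support: int = 4
    merge_gap: int = 0
    window_size: int = 100_000
    binning: str = "derive"  # "derive" | "published"
    element: str = "line1"
    cutoff: str | float = "auto"
    strata: str | None = "center"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if hasattr(obj, "summary") and hasattr(obj, "events"):  # SurvivalFit
        return {
            "summary": obj.summary.reset_index().to_dict(orient="list"),
            "n": obj.n,
            "events": obj.events,
            "strata": obj.strata,
            "ties": obj.ties,
        }
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(cfg).items() if k != "sample_reads"},
                    "stages": {}, "inputs": {}}

    # ---- stage: inputs ------------------------------------------------------
    if cfg.simulate is not None:
        sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulate)
        cohort = simulate_cohort(sim_cfg)
        paths = write_cohort(cohort, out / "cohort")
        report["inputs"] = {k: _checksum(v) for k, v in paths.items()}
        probes = cohort.probes
        manifest = sim_cfg.genome
        repeats = cohort.repeats
        arms = _arms_from_manifest(manifest)
        clinical = cohort.clinical
        profiles = cohort.profiles
        sample_reads = cohort.sample_reads
        input_reads = cohort.input_reads
        segments_in = None
    else:
        if cfg.probes is None:
            raise ConfigError("either a simulate block or a probes path is required")
        for key in ("probes", "segments", "repeats", "manifest", "cytobands",
                    "clinical", "profiles", "input_reads"):
            p = getattr(cfg, key)
            if p is not None:
                if not Path(p).exists():
                    raise ConfigError(f"{key} path does not exist: {p}")
                report["inputs"][key] = _checksum(p)
        try:
            probes = cna.ProbeSet.from_tsv(cfg.probes)
        except ValueError as exc:
            raise DataError(str(exc)) from exc
        manifest = (
            GenomeManifest.from_table(cfg.manifest)
            if cfg.manifest
            else _manifest_from_probes(probes)
        )
        arms = load_cytobands(cfg.cytobands) if cfg.cytobands else _arms_from_manifest(manifest)
        repeats = RepeatTrack.from_bed(cfg.repeats) if cfg.repeats else None
        clinical = read_clinical(cfg.clinical) if cfg.clinical else None
        profiles = pd.read_csv(cfg.profiles).set_index("sample") if cfg.profiles else None
        segments_in = cna.read_seg(cfg.segments) if cfg.segments else None
        sample_reads = {s: mbd.read_bed_intervals(p) for s, p in cfg.sample_reads.items()}
        input_reads = mbd.read_bed_intervals(cfg.input_reads) if cfg.input_reads else None

    # reuse a completed identical run
    report_path = out / "run_report.json"
    if report_path.exists():
        with open(report_path) as fh:
            prev = json.load(fh)
        if prev.get("config") == json.loads(json.dumps(report["config"], default=_jsonable)) and \
           prev.get("inputs") == report["inputs"]:
            logger.info("inputs and config unchanged; reusing completed run in %s", out)
            return prev

    # ---- stage: copy-number calling ----------------------------------------
    if segments_in is not None:
        segments = segments_in
    else:
        segments = []
        for s in probes.samples:
            segments.extend(
                cna.call_segments(
                    probes, s,
                    min_probes=cfg.min_probes, min_abs_log2=cfg.min_abs_log2,
                    probe_threshold=cfg.probe_threshold,
                    manifest=manifest, exclude_sex=cfg.exclude_sex,
                )
            )
    cna.write_seg(segments, out / "segments.seg")
    arm_abs = cna.call_arm_aberrations(segments, probes, arms, arm_min_probes=cfg.arm_min_probes)
    pd.DataFrame(
        [{"sample": a.sample, "arm": a.arm_label, "state": a.state, "probes": a.probes_in_state}
         for a in arm_abs]
    ).to_csv(out / "arm_aberrations.tsv", sep="\t", index=False)
    burden = cna.aberration_burden(segments, probes)
    burden.reset_index().to_csv(out / "burden.tsv", sep="\t", index=False)
    report["stages"]["cna"] = {
        "n_segments": len(segments),
        "n_loss": sum(1 for s in segments if s.state == "loss"),
        "n_arm_aberrations": len(arm_abs),
    }

    # ---- stage: breakpoints and CBPs ---------------------------------------
    bps = extract_breakpoints(segments, probes)
    cohort_size = len(probes.samples)
    cbps = find_cbps(bps, cohort_size, min_support=cfg.min_support, merge_gap=cfg.merge_gap)
    pd.DataFrame(
        [{"chrom": b.interval.chrom, "start": b.interval.start, "end": b.interval.end,
          "sample": b.sample, "side": b.side} for b in bps]
    ).to_csv(out / "breakpoints.bed", sep="\t", index=False)
    report["stages"]["breakpoints"] = {"n_breakpoints": len(bps), "n_cbps": len(cbps)}

    # ---- stage: repeat density ---------------------------------------------
    if repeats is not None:
        windows = genome_windows(manifest, repeats, size=cfg.window_size,
                                 include_sex=not cfg.exclude_sex)
        binning = PUBLISHED_BINNING if cfg.binning == "published" else derive_binning(windows["density"])
        for c in cbps:
            c.repeat_density = density(c.density_interval, repeats)
        cbps_to_frame(cbps).to_csv(out / "cbps.tsv", sep="\t", index=False)
        if cbps:
            enrichment = cbp_density_enrichment(cbps, windows["density"], binning)
            with open(out / "cbp_density_report.json", "w") as fh:
                json.dump(enrichment, fh, indent=1, default=_jsonable)
            report["stages"]["density"] = {
                "binning_edges": list(binning.edges),
                "cbp_mean_density": enrichment["cbp_mean_density"],
                "genome_mean_density": enrichment["genome_mean_density"],
                "trend_p": enrichment["trend_p"],
            }
        else:
            report["stages"]["density"] = {"note": "no CBPs at the configured support"}
    else:
        cbps_to_frame(cbps).to_csv(out / "cbps.tsv", sep="\t", index=False)
        report["stages"]["density"] = {"note": "no repeat track supplied; stage skipped"}
        binning = PUBLISHED_BINNING
        windows = None

    # ---- stage: MBD quantification -----------------------------------------
    if sample_reads and input_reads is not None:
        shells = mbd.build_windows(probes)
        if cfg.exclude_sex:
            shells = shells[~shells["chrom"].isin(manifest.sex_chroms)].reset_index(drop=True)
        mbd_summary = {}
        for s, reads in sample_reads.items():
            win = mbd.quantify(shells, reads, input_reads)
            win = mbd.cn_normalize(win, [g for g in segments if g.sample == s])
            try:
                win = mbd.log_standardize(win)
            except ValueError as exc:
                raise DegeneracyError(f"MBD standardization failed for {s}: {exc}") from exc
            win.to_csv(out / f"mbd_{s}.tsv", sep="\t", index=False)
            entry = {"n_windows": int(len(win)), "n_excluded": int(win["excluded"].sum())}
            if cbps:
                entry["cbp_mean_z"] = mbd.region_mean(win, cbps)
            if repeats is not None:
                win_d = mbd.add_window_density(win, repeats)
                per_cat, r = mbd.density_stratified_mean(win_d, binning)
                entry["density_z_correlation"] = r
            mbd_summary[s] = entry
        report["stages"]["mbd"] = mbd_summary
    else:
        report["stages"]["mbd"] = {"note": "no read sets supplied; stage skipped"}

    # ---- stage: associations ------------------------------------------------
    if profiles is not None:
        volcano = stats.volcano(profiles, arm_abs, element=cfg.element, state="loss",
                                alpha=cfg.alpha)
        volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
        assoc: dict = {"volcano_flagged": volcano.loc[volcano["flagged"], "arm"].tolist()}
        try:
            r, ci, p = stats.corr_burden(profiles, burden["loss_probe_count"], cfg.element)
            assoc["loss_burden_correlation"] = {"r": r, "ci": ci, "p": p}
            bp_counts = pd.Series(
                {s: sum(1 for b in bps if b.sample == s) for s in probes.samples}, name="bp"
            )
            r2, ci2, p2 = stats.corr_burden(profiles, bp_counts, cfg.element)
            assoc["breakpoint_correlation"] = {"r": r2, "ci": ci2, "p": p2}
        except ValueError as exc:
            raise DegeneracyError(str(exc)) from exc
        assoc["element_correlations"] = stats.element_correlations(profiles).to_dict(orient="list")
        report["stages"]["associations"] = assoc
    else:
        report["stages"]["associations"] = {"note": "no methylation profiles; stage skipped"}

    # ---- stage: survival ----------------------------------------------------
    if clinical is not None and profiles is not None:
        surv = survival_report(clinical, profiles, element=cfg.element,
                               cutoff=cfg.cutoff, strata=cfg.strata)
        surv_out = {k: v for k, v in surv.items() if k != "survival"}
        for origin, res in surv.get("survival", {}).items():
            res["km_high"].to_csv(out / f"km_high_{origin}.tsv", sep="\t", index=False)
            res["km_low"].to_csv(out / f"km_low_{origin}.tsv", sep="\t", index=False)
            surv_out[f"logrank_{origin}"] = {"chi2": res["logrank_chi2"], "p": res["logrank_p"]}
        report["stages"]["survival"] = surv_out
    else:
        report["stages"]["survival"] = {
            "note": "clinical table or profiles missing; survival stage skipped"
        }
        logger.warning("survival stage skipped: clinical table or profiles missing")

    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable, sort_keys=True)
    report = json.loads(json.dumps(report, default=_jsonable))
    return report


def _manifest_from_probes(probes) -> GenomeManifest:
    lengths = probes.df.groupby("chrom")["end"].max().to_dict()
    return GenomeManifest(
        {c: int(v) for c, v in lengths.items()},
        sex_chroms=frozenset(c for c in lengths if c.removeprefix("chr") in ("X", "Y")),
    )


def _arms_from_manifest(manifest: GenomeManifest) -> ArmMap:
    """Fallback arm map when no cytoband file is given: each chromosome split
    at its midpoint (p then q)."""
    arms = {}
    for chrom, length in manifest.lengths.items():
        mid = length // 2
        arms[chrom] = {
            "p": GenomicInterval(chrom, 0, mid),
            "q": GenomicInterval(chrom, mid, length),
        }
    return ArmMap(arms, manifest)
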