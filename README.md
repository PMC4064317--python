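# line1mm

Integrative analysis of global **LINE-1 hypomethylation**, **copy-number
loss** and **recurrent genomic breakpoints** in multiple myeloma (MM).

Global methylation of repetitive elements (LINE-1, Alu Ya5/Yb8,
satellite-α) declines during the progression of plasma-cell malignancy, and
LINE-1 hypomethylation in particular tracks the degree of genomic loss.
`line1mm` packages the full analysis chain behind that observation, for
anyone working with aCGH copy-number profiles, repeat annotations, MBD-seq
read sets and clinical follow-up:

1. **Copy-number calling** — a transparent run-threshold caller on probe
   log2 ratios (runs of ≥ 3 consecutive probes beyond a per-probe threshold
   with mean |log2| ≥ 0.5), arm-level aberrations (> 50 probes per arm) and
   per-sample aberration burden.
2. **Breakpoints and CBPs** — loss-boundary breakpoints as flanking
   probe-pair regions, and *common breakpoints* (CBPs): sweep-line regions
   where breakpoints from ≥ 4 distinct samples coincide.
3. **Repeat density** — LINE-1 density per 100,000 bp in arbitrary
   intervals, the five-category genome binning
   (0; 0.01–13.43; 13.44–26.35; 26.36–39.99; ≥ 40.00), and the
   Mantel–Haenszel linear-trend test `M² = (N−1) r²` for CBP-vs-genome
   density association.
4. **MBD-seq quantification** — inter-probe window read rates, input and
   copy-number normalization, log z-standardization, and region- or
   density-stratified methylation summaries.
5. **Association statistics** — Welch and Games–Howell group tests,
   per-arm volcano tables, Pearson correlations of methylation with
   `log10(burden + 1)`, ordered-group linear-trend contrasts.
6. **Survival** — ROC-derived methylation cutoff (closest point to the
   upper-left corner), Kaplan–Meier curves, log-rank tests, and stratified
   Cox proportional-hazards models.

A **synthetic cohort generator** (`line1mm.simulate`) produces complete toy
cohorts — probe matrices, segments, repeat tracks, read sets, methylation
profiles, clinical tables, plus ground truth — with the planted structure
the pipeline is designed to detect, so everything is testable end-to-end
without any download. The published list of 80 CBP regions, with their
LINE-1 densities and break frequencies, ships as a packaged table
(`line1mm.datasets.load_common_breakpoints`).

## Worked example

Simulate a 67-sample cohort and run the analysis chain:

```python
import pandas as pd
from line1mm import SimulationConfig, simulate_cohort, call_segments, \
    extract_breakpoints, find_cbps
from line1mm.repeats import cbp_density_enrichment, derive_binning, density
from line1mm.stats import corr_burden
from line1mm.survival import survival_report

cfg = SimulationConfig(seed=11, n_samples=67)
cohort = simulate_cohort(cfg)

segments = [seg for s in cohort.probes.samples
            for seg in call_segments(cohort.probes, s, manifest=cfg.genome)]
bps = extract_breakpoints(segments, cohort.probes)
cbps = find_cbps(bps, cohort_size=67, min_support=4)

binning = derive_binning(cohort.windows["density"])
for c in cbps:
    c.repeat_density = density(c.density_interval, cohort.repeats)
rep = cbp_density_enrichment(cbps, cohort.windows["density"], binning)
print(f"{len(cbps)} CBPs; mean LINE-1 density {rep['cbp_mean_density']:.1f} "
      f"vs genome {rep['genome_mean_density']:.1f} per 100 kb; "
      f"trend P = {rep['trend_p']:.2g}")

burden = pd.Series(cohort.truth["loss_burden"])
r, (lo, hi), p = corr_burden(cohort.profiles, burden)
print(f"burden-methylation r = {r:.3f} (95% CI {lo:.3f} to {hi:.3f}), P = {p:.2g}")

surv = survival_report(cohort.clinical, cohort.profiles, strata="center")
hr = surv["unadjusted"].summary.loc["hypomethylated"]
print(f"ROC cutoff {surv['cutoff']:.1f}% LINE-1 methylation; "
      f"HR {hr['hr']:.2f} (95% CI {hr['ci_low']:.2f}-{hr['ci_high']:.2f}), "
      f"log-rank P = {surv['survival']['collection']['logrank_p']:.3g}")
```

Output:

```
104 CBPs; mean LINE-1 density 36.8 vs genome 25.2 per 100 kb; trend P = 4e-09
burden-methylation r = -0.279 (95% CI -0.487 to -0.042), P = 0.022
ROC cutoff 37.8% LINE-1 methylation; HR 2.12 (95% CI 1.07-4.19), log-rank P = 0.0277
```

Reading the numbers: recurrent breakpoints concentrate in LINE-1-dense
windows (mean density well above the genome background, trend P ≪ 0.05);
samples with heavier copy-number loss have lower LINE-1 methylation
(negative Pearson r on the log burden); and patients below the ROC-derived
methylation cutoff die faster (hazard ratio above 1 with a significant
log-rank test) — the generator planted a true hazard ratio of 2.8 for the
hypomethylated half.

The same chain is available from the shell:

```sh
line1mm simulate --seed 11 --n-samples 67 --outdir cohort/
line1mm run-all --seed 11 --outdir run/          # full pipeline + report
line1mm cbp-density-report                        # packaged published table
```

`line1mm cbp-density-report` summarizes the packaged 80-region CBP table:
mean LINE-1 density 34.4 per 100,000 bp, minimum break frequency 6.0%
(the 4-of-67 recurrence floor), and the count of regions per density
category.

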