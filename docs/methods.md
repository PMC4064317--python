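# Methods

`line1mm` implements an integrative analysis linking global hypomethylation
of repetitive elements — LINE-1 above all — to copy-number loss, recurrent
genomic breakpoints, regional methylation decline and overall survival in
multiple myeloma (MM). This note documents the models and procedures, the
parameters that matter, what the synthetic cohort generator does and does
not emulate, and the numerical decisions taken where the design was open.

## Coordinate model

All coordinates are 0-based half-open internally. BED-style inputs pass
through unchanged. UCSC `cytoBand.txt` files are BED-like and also pass
through. Published tables with 1-based inclusive coordinates (the packaged
common-breakpoint list) are converted on read (`start - 1`). Chromosome
arms are assigned by interval midpoint: each probe or region belongs to
exactly one arm, which keeps arm-level probe counts a partition. Sex
chromosomes are flagged in the genome manifest and excluded from
copy-number and density analyses by default, reflecting their distinct
epigenetic regulation. The package is assembly-agnostic: the genome is
wholly described by a chromosome-length manifest plus optional cytobands.

## Copy-number calling

Proprietary aberration scores from vendor software have no open equivalent,
so segments are called with a transparent run-threshold scan: maximal runs
of consecutive probes on one chromosome whose log2 ratios all exceed `+t`
(gain) or fall below `-t` (loss) are candidates; candidates are kept when
they span at least `min_probes = 3` probes and their mean |log2 ratio|
reaches `min_abs_log2 = 0.5`. The per-probe run threshold `t` defaults to
0.2 — small enough that probes inside a true |log2| >= 0.5 event pass with
high probability at realistic probe noise (sd ~0.15), large enough that
three consecutive baseline probes rarely align in sign beyond it, and the
surviving false runs are removed by the mean filter. Probes with missing
ratios are dropped and terminate runs, so a segment is always a run of
observed consecutive probes. Pre-computed SEG-style segment tables can be
supplied instead, bypassing the caller.

Arm-level aberrations require strictly more than `arm_min_probes = 50`
probes inside same-state segments on one arm — the strict inequality
matters at the boundary (50 probes is not a call). Aberration burden is the
count of distinct probes covered by loss (resp. gain) segments per sample;
because segments are disjoint maximal runs this equals the sum of segment
probe counts.

## Breakpoints and common breakpoints (CBPs)

A copy-number-loss boundary is localized only to the gap between the last
probe outside the lost region and the first probe inside it. Each loss
segment therefore contributes up to two breakpoints, each represented by
the union footprint of the flanking probe pair; a boundary at a chromosome
end (no outside probe) yields none on that side. Only loss boundaries
generate breakpoints by default, since losses are the aberration class tied
to hypomethylation here; gains can be included via `states=("loss","gain")`
for exploration.

Recurrence across the cohort is found by a sweep-line over per-sample
merged breakpoint intervals: maximal regions where intervals from at least
`min_support = 4` distinct samples overlap become CBPs (a sample counts
once per region however many of its breakpoints fall there — recurrence
counts cases). Qualifying regions separated by at most `merge_gap`
(default 0) are merged. The break frequency is
`100 x supporting_samples / cohort_size`; with the reference design of 4
supporting samples in 67, the floor is 6.0%.

Two intervals are attached to each CBP. The *core* is the sweep-line
region itself — every internal position is covered by >= `min_support`
samples — and is what the brute-force per-base oracle verifies. The
*footprint* is the span of the supporting probe-pair breakpoint intervals.
Densities are scored on the footprint: cores can degenerate to a single
shared probe footprint (tens of bp) on which a per-100-kb density is
meaningless, whereas published CBP spans are probe-pair regions. This
choice is the package's own resolution of an under-specified merging rule
and is exposed via `CBP.density_interval`.

## Repeat density and the five-category binning

Density of a repeat family in an interval is the number of annotation
records overlapping it by >= 1 bp, per 100,000 bp. Counting records (i.e.
RepeatMasker fragments) rather than covered bases or prorated overlaps is
deliberate: published per-100-kb values exceed plausible full-length
element counts but match fragment counts. A midpoint-containment rule is
available (`rule="midpoint"`).

The genome is tiled into fixed windows (default 100 kb; the last window per
chromosome may be short). Window densities define a five-category ordinal
binning: category 1 is exactly zero; categories 2–5 split the positive
densities at their quartiles (linear-interpolated). The published bin edges
(13.43 / 26.35 / 39.99, category 5 at >= 40.00) ship as `PUBLISHED_BINNING` so
published categories reproduce without a genome-scale annotation download.
Upper edges are inclusive, matching the printed ranges.

CBP-vs-genome density association is tested with the Mantel–Haenszel
linear-trend statistic on the 2xK category table with rank scores:
`M^2 = (N - 1) r^2` on 1 df, where `r` is the Pearson correlation of row
and column scores over the N classified units. A calibration subtlety: the
genome row is a census (it has no sampling variability), so in finite
samples the test is conservative by roughly the factor
`n_census / (n_census + n_breakpoints)`. At genome scale (~tens of
thousands of windows against ~80 CBPs) the factor is negligible and the
test is calibrated; on a toy genome with a few hundred windows the same
test is conservative by design. Calibration experiments in
`line1mm.experiments` therefore use a genome-representative background
(20,000 windows drawn once from the generator's repeat model), while power
experiments run the full pipeline on the toy genome, where conservatism
only understates power.

## MBD-seq quantification

Regional methylation from MBD-enriched sequencing follows a four-step
normalization cascade over inter-probe windows (one window per adjacent
same-chromosome probe pair):

1. read counts per window, assigned by read midpoint (each read counts in
   at most one window), divided by window length — reads per nucleotide;
2. division by the matched input (non-enriched) rate, removing mappability
   and accessibility bias: `level = (rate_s + eps) / (rate_i + eps)` with a
   pseudo-rate `eps = 0.5 reads / length`; windows with fewer than one
   input read are flagged and excluded from standardization;
3. division by `CN / 2` with discrete copy number from the aCGH calls (1 in
   losses, 3 in gains, 2 elsewhere; a continuous `2 x 2^log2` mode is
   available), so halved coverage at halved copy number cancels — exactly,
   when the pseudo-rate floor is not engaged;
4. per-sample z-standardization of log levels, since normalized levels are
   approximately log-normal.

The whole-genome mean of z is 0 by construction, so the mean z over a
region set (e.g. CBPs) directly measures its deviation from the genome.
Density-stratified means report mean z per density category plus the
correlation of z with the ordinal category.

## Association statistics

Two-group comparisons use Welch's unequal-variance t-test; three or more
groups use Games–Howell pairwise comparisons (studentized-range reference
with Welch–Satterthwaite df per pair). Burden–methylation correlations are
Pearson on `log10(count + 1)` — base and pseudo-count are a package
decision, chosen so zero burdens stay defined — with Fisher-z 95% CIs.
Ordered-group trends (e.g. methylation across ISS stages) use the linear
polynomial contrast in a one-way model with rank scores and the pooled
within-group mean square; with two groups this is exactly the pooled t.
The per-arm volcano table reports the methylation difference
(with-aberration minus without) and Welch P per arm x state; rows with
fewer than two samples on either side are marked untestable. No
multiple-testing adjustment is applied by default — the aberration
variables are strongly inter-correlated and the analysis is exploratory —
but Benjamini–Hochberg is available (`adjust="bh"`).

## Survival

The methylation marker is dichotomized at the ROC-derived threshold:
candidate cutoffs are midpoints between sorted distinct marker values, the
outcome is vital status at end of follow-up, low marker values predict the
event, and the cutoff minimizing `(1-sens)^2 + (1-spec)^2` (closest point
to the upper-left corner) is chosen, ties broken toward the lower
threshold. The published cutoff from the original 74-patient cohort, 36.0%
LINE-1 methylation, ships as `PUBLISHED_LINE1_CUTOFF` because it cannot be
re-derived without patient-level data. Kaplan–Meier estimates carry
Greenwood variances; group differences use the log-rank test. Cox models
are fitted by stratified partial likelihood (optionally stratified by
center) with Efron tie handling by default; Breslow is selectable for
compatibility with software whose default differs (the two coincide on
untied data). Constant covariates raise immediately; extreme coefficients
are flagged as possible separation.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline is built to
detect, at toy scale (three autosomes of 20/15/10 Mb plus a flagged 5 Mb
sex chromosome; 100 kb windows; probes every 50 kb):

- **Repeat landscape** — per-window LINE-1 element counts are Poisson with
  gamma-distributed window means (shape 2, mean 25 per 100 kb) and an 8%
  zero-inflated fraction, spreading windows across all five density
  categories with a genome mean density in the 20s per 100 kb, comparable
  to genome-wide LINE-1 fragment densities; Alu records are a uniform
  background.
- **Copy-number loss** — each sample receives Poisson(6) loss segments (and
  Poisson(2) gains) of 4–30 probes; both loss boundaries land in probe gaps
  drawn with probability proportional to `exp(beta x (category - 1))`,
  `beta = 0.4` by default — a moderate enrichment chosen so recurrent
  breakpoints arise preferentially in LINE-1-dense windows, as observed.
  Probe log2 ratios are the true segment mean (−0.8 loss, +0.7 gain) plus
  N(0, 0.15) noise, so the caller is exercised nontrivially.
- **Methylation link** — LINE-1 % = 48 − 6 x log10(loss probes + 1) +
  N(0, 5), clipped to [0, 100]; the other elements are noisy affine
  transforms of LINE-1, reproducing the strong positive inter-element
  correlations. The induced burden–methylation correlation is around −0.5
  at the default settings.
- **MBD reads** — window read counts are Poisson with mean
  `depth x (methylation/100) x (CN/2)` for the enriched channel and
  `depth` for input (depth 3 reads/window by default), with optional
  per-category or per-region methylation effects for planted-signal
  studies.
- **Survival** — exponential event times with baseline hazard ln2/1500
  per day (median OS about four years), multiplied by the configured hazard
  ratio (default 2.8) for samples below the cohort *median* methylation —
  the median, not the ROC cutoff, so the ground truth stays independent of
  the estimator under test — under independent exponential censoring at the
  baseline rate (roughly 40% censored). ISS stage is drawn with
  hypomethylation shifted toward stage 3.

A fixed seed makes the cohort bit-reproducible, and every emitted file
(probe matrix, SEG segments, repeat BED, read BEDs, clinical and profile
CSVs, ground-truth JSON) round-trips through the package readers.

What the generator does **not** emulate: real read-level sequence content
and mappability structure, GC waves and other array artifacts, subclonal or
allele-specific copy number, focal amplifications, inter-individual
germline CNVs, translocation biology at the IGH locus, and covariate
confounding between methylation and clinical variables beyond the planted
links. Passing recovery tests therefore demonstrates that the estimators
recover the planted generative structure at realistic sizes and noise —
not that real MM data satisfy that structure.

## Reproduction experiments and problem sizes

`line1mm.experiments` (driven by `scripts/acceptance.py`) re-runs, at the
original study's scale, the checks that the cohort-specific published
numbers cannot provide (patient-level data are not public): trend-test
null calibration (1,000 replicates of 80 uniform breakpoints against a
20,000-window background), enrichment power (100 full-pipeline cohorts of
67 samples), correlation recovery (200 replicates of a planted r = −0.5 at
n = 67), planted regional hypomethylation in the MBD cascade (6 samples),
and Cox CI coverage / log-rank power (500 cohorts of n = 74 at true
HR 2.8). These sizes keep each experiment in the seconds-to-a-minute range
while leaving Monte-Carlo error well inside the documented tolerance
bands.

## Known limitations

- The run-threshold caller is not a change-point method; very noisy probes
  or low-amplitude mosaic events that vendor algorithms might aggregate
  will be fragmented or missed. The stated acceptance filters (3 probes,
  |mean| >= 0.5) are honored exactly.
- The CBP merging rule (sweep-line + `merge_gap`) is one defensible reading
  of an under-specified cross-sample matching procedure; alternative rules
  (exact probe-pair identity) would produce slightly different region
  boundaries.
- Fragment-count density treats a fragmented element as several records;
  with merged annotations the derived quartile binning shifts accordingly.
- The ROC outcome is vital status at end of follow-up; time-dependent ROC
  is out of scope.
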