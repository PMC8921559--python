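# Methods

This note records the statistical models, parameter choices and known
limitations behind `aelink`, in the spirit of a package vignette.

## Study design assumed

All differential stages assume a *paired* design: each patient contributes
exactly one tumor and one adjacent-normal sample, and inference is on the
within-patient differences. The enhancer catalog assumes per-sample peak or
chromatin-state calls are already available (peak calling and segmentation
are upstream of this package). Coordinates are 0-based half-open
throughout; 1-based positions appear only in human-readable reports.

## Enhancer catalog

A whole H3K4me1 peak is classified *active* when it overlaps any H3K27ac
peak by at least one base, otherwise *primed*; for a sample without H3K27ac
data the state is *unknown* (the peak still contributes to the catalog).
Classifying the whole peak rather than the overlapping sub-region is a
deliberate choice: sub-region classification would fragment peaks and
change merge behaviour; the catalog itself is state-agnostic, so only the
per-sample active/primed summaries depend on it.

Union-merge coalesces overlapping *and* book-ended intervals (standard
merge semantics). Filters applied to merged intervals: length < 50 bp, and
≥ 1 bp overlap with any promoter, where the promoter spans 1,500 bp
upstream to 500 bp downstream of the TSS, oriented by strand. "Gene body"
for the genic/intergenic partition is the transcript span
[tx_start, tx_end). Concurrence counts distinct samples contributing at
least one overlapping source interval; it is monotone in the sample set.
The state-BED vocabulary is a configurable label map with defaults
`active_enhancer → active`, `poised_enhancer`/`primed → primed`; all other
labels are dropped with a warning.

## Differential testing

Expression features are normalised to fragments per million
(count / library size × 1e6) and transformed as log2(FPM + 1); the
pseudocount of 1 keeps zero counts at zero and is the package's convention
for both eRNA and gene matrices. Each feature gets a paired *t*-test on the
per-patient tumor − normal differences; the effect estimate is the mean
difference on the log2 scale (an approximate log2 fold change). BH-FDR is
applied across features. Degenerate features are mapped deterministically:
all-zero differences → p = 1; zero variance with nonzero mean → p = 0; both
are logged. Gene differential expression uses the same paired test as the
eRNA stage — a single, self-contained test for the whole pipeline rather
than a count-model fit with dispersion shrinkage; with 30+ pairs and the
|log2FC| > 0.5, FDR < 0.05 thresholds the calls are very similar in
practice, but small-n behaviour will differ from shrinkage-based callers.

Methylation betas are tested on the raw scale. A DML is a CpG with
FDR < 0.05 and |mean Δβ| ≥ 0.1; a DMR is a maximal run of ≥ 5
same-direction DMLs whose consecutive genomic gaps are ≤ 500 bp. The three
knobs (`min_cpgs`, `max_gap`, `min_delta`) are explicit parameters with
those defaults; `min_cpgs = 5` harmonizes with the genic-DME "≥ 5 CpGs"
criterion. This run-scan caller is intentionally simple — no smoothing, no
beta-binomial likelihood — and is defined precisely enough to be checked
against an exhaustive enumeration oracle in the tests.

## Linking

Intergenic links: candidates are (DEE, DEG) pairs on one chromosome with
|TSS − enhancer center| ≤ 1 Mb; Spearman correlation (average ranks for
ties, *t*-approximation p) is computed across all samples, tumor and
normal. The Bonferroni family is the set of candidate pairs actually
tested — the most conservative defensible choice. The ρ ≥ 0.7 criterion is
positive-only; the genic criterion |ρ| ≥ 0.5 is sign-free, so
methylation–expression links of either sign are kept. Direction
consistency between a DEE and its linked DEG is *not* imposed beyond the
correlation gate.

Genic DMEs measure distance from the nearest enhancer edge to the TSS
(intergenic links measure from the center); "≥ 5 CpGs" counts CpGs inside
the enhancer ∩ DMR overlap; enhancer methylation per sample is the mean
beta over the CpGs inside the whole enhancer interval.

Super-enhancer clusters chain same-direction linked DEEs along a
chromosome while consecutive gaps are ≤ 50 kb and each new member shares at
least one linked gene with the chain. The 50 kb default is chosen so that
a cluster with ~10 kb mean spacing (35 enhancers over ~344 kb) chains into
one unit. The reported gene set is the union of members' linked genes;
`strict=True` restricts it to genes linked to every member. Constant
vectors in any correlation are mapped to ρ = 0, p = 1 with a log message.

## Replication

DEE concurrence requires same-direction significance in the replication
cohort — direction-blind counting would inflate concurrence. Link
concurrence additionally requires the cohort's own link test to pass
(ρ ≥ 0.7, corrected p < 0.01). Array-platform replication classifies a
pair as a type I failure when the enhancer contains zero platform-covered
CpGs (coverage is supplied as a positions table so array sparsity can be
emulated), otherwise success iff differential methylation, differential
expression and the correlation are all significant, otherwise type II.
Rates are kept at full precision and rounded to two decimals only in
reports; the platform-adjusted rate never falls below the raw rate. An
empty category reports NaN rates, never zero.

## Topology confirmation, enrichment, risk score

TAD confirmation uses point containment (enhancer center and TSS) in any
single TAD; overlapping TADs are allowed; a strict whole-interval mode is
available. Loop confirmation requires ≥ 1 bp enhancer–anchor overlap with
the TSS inside the other anchor, in either orientation. Enrichment is a
plain upper-tail hypergeometric test over a user-supplied background and
GMT gene sets with BH-FDR; no gene-set database is bundled.

The risk score is a fixed linear combination of six genes (PLOD2 0.424,
HOXD9 0.109, BOP1 0.184, RAB26 −0.134, KLRK1 −0.185, RGL4 −0.0547) on
whatever normalized expression scale the caller supplies; absolute cutoffs
are therefore scale-dependent. Coefficient fitting (Cox, LASSO) is out of
scope — the coefficients are constants, overridable via configuration.
The optimal cutoff scans observed scores between the 10th and 90th
percentiles (guarding against degenerate splits), skips candidates leaving
a group without events, minimizes the log-rank p-value and breaks ties
toward the cutoff nearest the median score. The log-rank statistic is the
classic (O − E)²/V form with the hypergeometric variance at each distinct
event time; it is cross-checked against lifelines in the tests.

## Synthetic data generator

The generator emulates the design of the kind of study the package
targets: 11 ChIP-seq samples
(one without H3K27ac), 33 tumor/normal RNA-seq pairs, ≈ 32 % of a sample's
enhancers active, and a majority of catalog enhancers present in ≥ 2
samples. Genome layout places non-overlapping genes and four template
classes — intergenic, genic (inside gene bodies, clear of promoters),
deliberately promoter-resident, and deliberately sub-50 bp — so the
catalog's filters are exercised by construction. Per-sample peaks are
±20 bp jitters of the template (sub-50 bp templates stay exact so the
length filter sees their planted size).

Counts are negative binomial via a gamma–Poisson mixture with a shared
per-feature dispersion (default 0.1). The paired structure is a per-pair
lognormal sequencing-depth factor folded into the *recorded library
sizes*, so per-million normalisation cancels it exactly and unplanted
features remain uncorrelated — this keeps the null clean for type-I-error
and linking-precision checks. Planted differential features shift the
tumor mean by ±`effect_lfc` (default 2 log2 units) and carry per-patient
effect heterogeneity; a planted link *shares* that tumor latent factor
between the enhancer and its target gene. The factor's scale is
τ = σ·√(ρ/(1−ρ)), where σ² is the expected log2-count noise variance, so
the within-tumor correlation targets `link_rho_target` (default 0.95);
the realized Spearman across all samples is targeted, not exact
(median ≈ 0.75–0.85 under defaults). The same heterogeneity given to
*unlinked* planted features (independently) prevents spurious candidate
pairs from correlating through group separation alone — without it, any
two same-direction differential features would pass the ρ ≥ 0.7 gate.

Methylation betas are clipped normals (sd 0.08) around group means; a
planted DMR shifts the tumor mean by ±0.3 over the CpGs of an enhancer
±100 bp. DMEs are planted only on genic templates present in ≥ 2 ChIP
samples (they would otherwise be unrecoverable by definition), and their
linked gene's expression shares the methylation latent factor with a sign
consistent with the planted direction pair. TADs start as a `tad_size`
tiling whose boundaries are then moved off the spans of links chosen for
containment (a configured fraction, default 0.7); the *realized*
membership of every planted link is recorded in the ground truth, so
downstream scoring never assumes the requested fraction was achieved.
Survival times are exponential with hazard either proportional to the
six-gene risk score or jumping at a planted score threshold; censoring is
uniform administrative.

What the generator does not emulate: read-level data, genomic sequence,
realistic chromatin-state transition structure, batch effects, and
library-preparation biases. Passing tests therefore demonstrate that the
pipeline's logic and thresholds behave as specified under a controlled
generative model — not that the thresholds are optimal for any particular
real dataset.

## Problem sizes and determinism

The shipped tests and the results script run studies of 2 chromosomes ×
3–10 Mb, 60–700 enhancer templates, 30–33 sample pairs, ~10–40 k CpGs and
200 survival patients — sizes chosen so a full run completes in seconds
while leaving ≥ 500 features for null-calibration checks and ≥ 20 planted
links for precision estimates. All randomness flows from a single
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
output files.

## Known limitations

- The paired *t*-test assumes approximately normal log-scale differences;
  very low counts or heavy contamination would call for a count model.
- The DMR caller does not merge across direction changes and has no
  smoothing; isolated noisy CpGs inside a planted region can split a run.
- Replication classification takes the cohort's three significance
  verdicts as given; it does not re-derive them from raw array data.
- The Bonferroni family grows with the candidate set, so adding
  non-differential features to the expression matrices does not change
  the family, but adding DEEs/DEGs does.
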