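# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `clipsplice`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; no empirical claim below goes
beyond what those runs verify.

## Splicing events and their comparison

A cassette (skipped) exon is represented by three genomic intervals —
genomically-left flanking exon, alternative exon, genomically-right
flanking exon — on 0-based half-open coordinates, with per-replicate
inclusion (IJC) and skipping (SJC) junction read counts for two groups.
Group 1 is the control and group 2 the target condition, so a negative
inclusion-level difference (ΔPSI = PSI₁ − PSI₂) means the exon is
*included* in the target condition, a positive ΔPSI that it is *excluded*.

Filtering conventions:

* **Coverage.** An event is analyzable when IJC + SJC ≥ 10 in *every*
  replicate of both groups (inclusive ≥, per-replicate). "Counted reads"
  is read as the total junction support for the event; applying the bound
  separately per junction class was the main alternative and is noted as
  a deliberately resolved ambiguity.
* **Significance.** FDR < 0.05 and |ΔPSI| > 0.1, both strict.
* **Identity across runs.** The canonical event key is
  (chrom, strand, left-flank donor, alt-exon acceptor, alt-exon donor,
  right-flank acceptor) — only the four junction-defining coordinates, so
  the same junction annotated with different flank outer boundaries in
  two rMATS runs still matches. Duplicate keys within one table keep the
  row with the larger total junction support (deterministic, logged).
* ΔPSI is always taken from the table, never recomputed from counts.

Cross-dataset comparison joins on the event key (events must pass
coverage in both datasets), cross-tabulates significance flags, and uses
the conditional two-sided Fisher exact test with the sample odds ratio
(n₁₁·n₀₀)/(n₁₀·n₀₁); an empty denominator is reported as infinite with a
flag. ΔPSI agreement uses Spearman correlation.

## Sub-region decomposition and strand handling

Each event decomposes into five transcript-oriented sub-regions plus the
full junction span. rMATS labels flanks by genomic order, so on the minus
strand the genomically-left flank is the transcript's *downstream* exon;
the decomposition swaps labels (never coordinates) on the minus strand.
This is the single most consequential convention in the package and is
pinned by a coordinate-mirror invariance test: reflecting every
coordinate (x → L − x) and flipping every strand leaves all enrichment
results unchanged. Zero-length introns (abutting exon annotations) are
dropped rather than emitted as empty intervals.

## Peak handling and positional enrichment

CLIP peaks carry log₂ fold enrichment of IP over size-matched input and a
−log₁₀ P. Significance thresholds are strict (>): 5/5 for TDP-43 and 3/3
for NOVA1, NOVA2, RBFOX2. The overlap predicate everywhere is: same
strand, ≥ 1 shared base, half-open arithmetic (matching BED intersection
semantics). An event counts at most once per region regardless of how
many peaks it contains (the `-u` convention of bedtools-style
intersection).

Enrichment of a selected event set (significant events, optionally
restricted to one splicing direction) against the coverage-passed
background is the hypergeometric upper tail including the observed count,
P(X ≥ k) with X ~ HG(N = background size, K = background events carrying
a peak in the region, n = selected size). Fold enrichment is
(k/n)/(K/N), undefined (flagged) when K = 0. Proximal-window variants
restrict introns to the window adjacent to the alternative exon in
transcript orientation; the window size is a free parameter because no
canonical value exists.

Gene-region annotation of peaks uses a fixed priority
(CDS > 3'UTR > 5'UTR > noncoding exon > intron > intergenic, longest
overlap breaking ties within a class). The priority is configurable; it
is a simplification of richer annotators whose exact ordering is not
reproducible here.

k-mer enrichment compares empirical k-mer frequencies of foreground
sequences against a user-supplied background with a one-sample binomial
z: z(w) = (f_fg − f_bg)/√(f_bg(1 − f_bg)/N_fg), k-mers absent from the
background receiving pseudo-frequency 1/(N_bg + 4^k). T and U are
identified; windows containing N are skipped. The background set is the
caller's choice (shuffled sequences, input reads, …) — the method makes
no assumption about it.

## Signature clustering

The ΔPSI matrix takes every event significant in ≥ 1 anchor dataset as a
row and each dataset as a column. Events absent from (i.e., not passing
coverage in) a dataset are imputed 0 — "no change", the conservative
choice for clustering — with an imputation mask retained so that cluster
medians can exclude imputed entries (they do whenever ≥ 50% of a
cluster's entries in that dataset are observed; otherwise the median is
over all entries and flagged). K-means uses Euclidean distance with
init='random', k = 8, n_init = 10, max_iter = 300, random_state = 42 — a
deliberately fixed configuration for reproducibility, not an optimized
one.

Cluster signatures formalize the gain/loss-of-function reading of median
patterns: **LOF** when all disease-dataset medians share one sign at
|median| ≥ 0.025, the knockout median has the same sign, and the
overexpression median the opposite sign (both at magnitude); **GOF** for
the mirror image; **dataset_specific** when disease medians disagree in
sign but at least one is material; **no_change** when everything is below
magnitude; **mixed** otherwise. The magnitude threshold 0.025 is a
configurable formalization — the qualitative labels it reproduces have no
published numeric rule. The classifier is sign-symmetric: negating every
median preserves the class.

## Insolubility screen

Per protein: fold change = mean(LFQ + 1)_target / mean(LFQ + 1)_control
(the +1 pseudocount is the missing-data handling; zeros are retained,
nothing is imputed) and two-sided Welch's t on log₂(LFQ + 1). Hits
require P < 0.05 and fold change ≥ 1.5; the comparator is exposed because
inclusive and strict readings of the cutoff both occur in practice.
Proteins with zero variance in both groups after the transform get P = 1.

The specificity null enumerates every mixed relabeling that places half
of each group on either side — all C(6,3)² = 400 ordered splits for a 6v6
design — runs the identical screen on each, and reports the distribution
of null hit counts plus observed/mean ratio. Any relabeling identical to
the true labels or their swap would be excluded; for mixed splits none
is, so all 400 splits are informative. At the default generator
conditions the observed/null ratio has expectation ≈ 5 — the screen's
specificity margin at that noise level, substantially smaller than what
lower-noise real data can show.

## Tissue quantification

Cytoplasmic MFI is the area-weighted remainder
(MFI_soma·A_soma − MFI_nuc·A_nuc − MFI_lip·A_lip)/A_cyt with
A_cyt = A_soma − A_nuc − A_lip; the identity
MFI_soma·A_soma = Σ compartment MFI·area holds exactly before clamping,
and negative results (measurement noise) are clamped to 0 with a flag.
Neurons require soma area strictly > 1000 µm². Channel MFIs are
normalized to the beta-III-tubulin MFI of the lipofuscin-free soma — the
soma minus lipofuscin only, nucleus included — which cancels
per-record multiplicative factors exactly (scale-invariance is tested).

Inter-individual variance reduction is reported on per-patient neuron
means as 100·(1 − relvar_normalized/relvar_raw) where relvar is the
across-patient variance divided by the squared across-patient mean.
The relative (CV²-type) form is used because raw and normalized MFIs
live on different scales; a raw variance ratio would report a near-100%
"reduction" for any rescaling and would not be ≈ 0 in the absence of
patient-level technical variation. This estimator is noisy at small
donor counts (it is a ratio of correlated variance estimates), so its
no-technical-factor calibration is checked on synthetic cohorts of 25
donors × 30 neurons, while the planted-factor check runs at the default
cohort size (7 control donors of 20 neurons, where it exceeds 50% in
every seeded run).

Mixed-model and nested-ANOVA machinery is deliberately not reimplemented:
within-cohort TDP-43-status comparisons aggregate to per-patient medians
and use an exact sign-flip permutation test on the paired differences.
This changes P values relative to mixed-effects fits but not directions.

Expression analysis converts NOVA1/STMN2 levels to z-scores anchored on
the controls of each dataset (≥ 2 controls with nonzero SD required);
ALS samples with STMN2 z < −2 (strict) form the STMN2-low class, controls
are always regular. Group comparisons use Kruskal-Wallis plus pairwise
two-sided rank-sum tests (no multiplicity adjustment by default,
Bonferroni optional); correlations are Spearman.

## Statistical primitives

Two-sided P values are doubled one-tails capped at 1. The exact
Mann-Whitney path assigns midranks and enumerates all rank assignments
whenever combined n ≤ 12 or the assignment count is ≤ 10⁶, so ties are
exact; larger designs use the normal approximation with tie correction,
and the method used is always reported. Spearman uses full permutation
enumeration for n ≤ 9. The paired sign-flip test enumerates all 2ⁿ sign
assignments (n ≤ 20). Hypergeometric tails, Fisher's exact test,
Welch's t, and Kruskal-Wallis delegate to scipy behind the module
surface; the exact paths are verified against independent brute-force
enumeration oracles in the test suite.

## Synthetic data: what it models and what it does not

Every generator expands one global seed into independent per-component
child streams, so outputs are byte-deterministic and sub-generators are
independently reproducible. Defaults follow the study design where it is
stated — 6 vs 6 proteomics samples, 4 replicates per RNA-seq group,
9 sALS / 7 control donors — and otherwise sit at values chosen once for
realistic, non-saturating power:

* **Cassette events** (1000 events, depth 100, 20% carrying |ΔPSI| = 0.3
  effects, beta-distributed replicate PSI at concentration 100): junction
  counts are binomial with length-weighted inclusion probability; the
  table's P comes from Welch's t on replicate PSI estimates with BH
  correction — a simple location test, *not* a splicing likelihood model.
  The pipeline only consumes the table's columns, so the generator's
  statistical fidelity matters only for calibration tests. Datasets can
  share a coordinate universe (`coord_seed`) so cross-dataset joins and
  the clustering matrix are meaningful.
* **Peaks**: background peaks uniform over junction spans (rate 0.1 per
  event); planted peaks (rate 0.6) sit at a reproducible "binding site" —
  introns anchored at the boundary adjacent to the alternative exon,
  exons at their center, ±10 bp jitter — so replicate peak sets overlap
  the way fixed binding sites do. Scores are drawn above the significance
  cutoffs.
* **LFQ**: lognormal intensities (log₂ base level ~ N(20, 2)), 50 of
  1000 proteins with a +2 log₂ target-group shift, replicate noise sd 0.5
  (log₂), optional zero-inflation (default off).
* **Neuron cohorts**: compartment intensities are built bottom-up so the
  conservation identity holds exactly; a per-donor lognormal technical
  factor (sd 0.5) scales all channels, per-donor biological variability
  is channel-specific (sd 0.15; 0.03 for the structurally stable
  tubulin), per-neuron brightness (sd 0.12) is shared across channels
  with a channel residual (sd 0.06). Planted biology mirrors the
  disease pattern: cytoplasmic NOVA1 up (×1.5) in disease neurons
  retaining nuclear TDP-43, nuclear NOVA1 down (×0.7) and nuclear TDP-43
  down (×0.3) in neurons that lost it.
* **Expression**: controls draw independent latent normals; disease
  samples draw from a bivariate normal (ρ = 0.7); a 25% subgroup shifts
  the STMN2 latent down 3 control SDs (NOVA1 down 1 SD), creating the
  STMN2-low class with reduced NOVA1.
* **Sequences**: uniform-random background; each foreground sequence
  carries one planted motif (default TCAT, echoing the YCAY preference;
  GCATG is the natural alternative for RBFOX-style analyses).

What passing tests on these data do **not** show: robustness to real
rMATS likelihood behavior, overdispersed or batch-structured proteomics
missingness, segmentation errors or autofluorescence misclassification in
imaging, annotation errors in gene models, or non-monotone
expression-correlation structure. The generators plant clean, known
effects; they validate the inference chain, not the upstream assays.

## Problem sizes

Default test and acceptance runs use 300–700 events per dataset, 50–100
seeded replicates for recovery rates, 400-split exhaustive shuffle nulls,
1000-rep type-I calibrations, and cohorts of 7–25 donors — sizes at which
every planted structure is comfortably identifiable and the whole suite
runs in well under a minute per module.
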