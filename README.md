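# clipsplice

Downstream-inference toolkit for studies linking RNA-binding-protein (RBP)
biology to aberrant alternative splicing in ALS: NOVA1/NOVA2/RBFOX2/TDP-43
binding maps, cassette-exon splicing changes, proteomic insolubility, and
single-neuron fluorescence quantification. The package is aimed at
computational biologists who have the standard upstream outputs in hand —
rMATS-style cassette-exon tables, eCLIP peak calls, label-free proteomics
(LFQ) matrices, per-neuron fluorescence measurements — and need the
downstream statistics reproducibly, plus seeded synthetic generators to
validate every stage against planted ground truth.

## What it computes

**Splicing events** (`as_events`). Parses rMATS `SE.MATS.JC.txt`-dialect
tables; events must carry ≥ 10 junction reads (IJC + SJC) in every
replicate; significant events satisfy FDR < 0.05 and |ΔPSI| > 0.1.
A canonical key built from the four junction-defining coordinates lets the
same cassette exon be matched across independent rMATS runs; dataset pairs
are compared by Fisher's exact test on the joined background (odds ratio
(n₁₁·n₀₀)/(n₁₀·n₀₁)) and Spearman correlation of ΔPSI.

**CLIP peaks** (`clip_peaks`). BED6+2 peaks (log₂ fold enrichment over
size-matched input, −log₁₀ P) thresholded strictly — log₂FC > 5 and
−log₁₀P > 5 for TDP-43, > 3 and > 3 for NOVA1/NOVA2/RBFOX2; peak and
target-transcript sharing between datasets; priority-based gene-region
annotation; k-mer Z-score enrichment
z(w) = (f_fg − f_bg) / √(f_bg(1−f_bg)/N_fg) against an empirical
background.

**Positional enrichment** (`splice_enrichment`). Each cassette event is
decomposed into transcript-oriented upstream exon / upstream intron /
alternative exon / downstream intron / downstream exon (labels swap on the
minus strand; coordinates do not). Enrichment of peak-bearing events in a
selected set against the coverage-passed background is the hypergeometric
upper tail P(X ≥ k), X ~ HG(N, K, n), stratified by splicing direction
(negative ΔPSI = inclusion in the target condition).

**Signature clustering** (`clustering`). Events significant in ≥ 1 anchor
dataset form a ΔPSI matrix (missing entries imputed 0 with a mask),
clustered by k-means (init='random', k=8, n_init=10, max_iter=300,
random_state=42). Cluster medians against overexpression/knockout
datasets yield gain/loss-of-function calls: LOF = disease agrees with
knockout and opposes overexpression; GOF is the mirror image.

**Insolubility screen** (`insolubility`). Per protein:
fold change = mean(LFQ+1)_target / mean(LFQ+1)_control, Welch's t on
log₂(LFQ+1); hits at P < 0.05 and fold ≥ 1.5. The specificity control
re-runs the identical screen on all 400 mixed relabelings (3+3 vs 3+3 for
a 6v6 design) and compares the true-label hit count with that null.

**Tissue quantification** (`tissue`). Lipofuscin-corrected cytoplasmic
MFI = (MFI_soma·A_soma − MFI_nuc·A_nuc − MFI_lip·A_lip)/A_cyt; soma-area
> 1000 µm² filter; beta-III-tubulin normalization with inter-individual
variance-reduction reporting; within-patient matched comparison of neurons
by TDP-43 status (exact sign-flip test); control-anchored NOVA1/STMN2
z-scores with the STMN2-low class at z < −2.

**Synthetic data** (`synthetic`). Seeded, byte-deterministic generators
for every input above with planted, recoverable truth tables.

## Worked example

```bash
clipsplice simulate --preset als-mn --seed 5 --outdir demo
clipsplice as-filter demo/ALS1.SE.MATS.JC.txt --out demo/ALS1.filtered.tsv
```

prints

```
{"parsed": 1000, "coverage_passed": 953, "significant": 159}
```

— of 1000 generated cassette events, 953 carry ≥ 10 junction reads in
every replicate and 159 pass FDR < 0.05 with |ΔPSI| > 0.1 (the generator
plants effects in 20% of events; some are lost to count noise and the
coverage filter). Then

```bash
clipsplice enrich demo/ALS1.SE.MATS.JC.txt demo/NOVA1.rep1.peaks.bed --region upstream_intron --direction included
```

prints the enrichment row for NOVA1 peaks in upstream introns of exons
included in the target condition:

```
         region direction  n_background  k_background  n_selected  k_selected  fold_enrichment  p_hypergeom  fold_defined
upstream_intron  included           953            89          81          55         7.270773 1.612312e-45          True
```

55 of 81 included significant events carry a NOVA1 peak in their upstream
intron versus 89 of 953 background events — a 7.3-fold enrichment with
hypergeometric P ≈ 1.6e-45, recovering the planted binding pattern. The
insolubility screen:

```bash
clipsplice insoluble demo/lfq.csv demo/lfq_groups.csv --null --out demo/hits.tsv
```

```
{"n_proteins": 1000, "n_hits": 62, "null_mean": 11.885, "observed_over_null": 5.2166...}
```

62 proteins pass the screen under the true labels versus a mean of ~11.9
under shuffled labels — a ~5-fold label-specific excess.

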