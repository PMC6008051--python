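# muscletx

Skeletal muscle is not one tissue: limb, head, trunk, cardiac and
smooth muscles each maintain distinct transcriptional programs, and
bulk RNA-seq atlases across many muscles show that over half of all
transcripts differ somewhere between tissues. `muscletx` is a tested,
reusable implementation of the analysis pipeline behind such an atlas,
for researchers who want to reproduce, stress-test or extend each
stage on their own count matrices — or on fully synthetic data with
planted, machine-readable ground truth.

## What the pipeline computes

* **Normalization** — FPKM with mitochondrial depth exclusion:
  `FPKM_ij = 10^9 · c_ij / (l_i · N_j)`, where `N_j` sums unique reads
  over *nuclear* transcripts only, so tissue-to-tissue differences in
  mitochondrial load cannot deflate nuclear expression. Log scale is
  `log2(FPKM + 1)` throughout.
* **Differential expression** — one-way fixed-effects ANOVA per
  transcript across a tissue subset on log expression, Benjamini–
  Hochberg q-values per analysis, and a max/min fold-change filter on
  raw-FPKM tissue means. Default call: q < 0.01, fold change > 2,
  among transcripts with mean FPKM > 1 in at least one tissue.
* **Similarity structure** — Euclidean distances between tissue-mean
  profiles, deterministic complete-linkage dendrograms (newick
  export), gene-family subsets (e.g. *Myh*, *Hox*), row Z-scores.
* **Principal-axis analysis** — PCA of samples over expressed
  transcripts (centering only), per-transcript Pearson correlation
  with PC1, and stratified-bootstrap 99% confidence intervals.
* **Fiber type** — per-tissue *Myh* composition (percent of
  Myh-aligned reads per isoform) and marker-gene R² panels against
  *Myh4*/*Myh7*.
* **Specificity & overlays** — the tau tissue-specificity index,
  `tau = Σ_i (1 − x_i/x_max)/(n−1)`, plus Venn overlays with disease,
  drug-target and secreted-protein gene lists and a myokine-candidate
  filter (secreted ∩ DE, FPKM > 10).
* **Cross-species concordance** — ortholog-paired expression R²,
  shared-DE overlap, sign concordance of log fold changes, and sex-DE
  fractions.
* **Junction discovery** — splice junctions absent from the annotated
  intron set, ranked by read support and classified as exon-skipping
  vs novel-exon/site candidates; BED6 export.
* **Synthetic data** — negative-binomial counts over log-normal tissue
  means with a latent fast/slow fiber axis driving *Myh*-like genes,
  planted DE, tissue-varying mitochondrial load, planted novel
  junctions, and a two-species pair with an exact direction-
  concordance quota. Every planted fact is returned as ground truth.

## Worked example

```python
from muscletx import (SimConfig, simulate_dataset, compute_fpkm,
                      log_transform, anova_de)

dataset, truth = simulate_dataset(SimConfig(seed=1))
fpkm = compute_fpkm(dataset)
de = anova_de(log_transform(fpkm), fpkm.values, dataset.samples)
print(dataset.counts.shape)
print(int(de["significant"].sum()), "of", len(de), "transcripts DE")
```

prints

```
(2000, 96)
1552 of 2000 transcripts DE
```

2,000 transcripts across 16 muscles (11 skeletal, 2 cardiac, 3 smooth)
× 6 replicates; with the default class-level expression shifts and the
fast/slow axis switched on, most transcripts genuinely differ between
some pair of tissues, so the ANOVA calls 1,552 of 2,000 significant at
q < 0.01 and fold change > 2 — the same qualitative picture a real
multi-tissue muscle atlas gives. Disabling every planted effect
(`de_fraction=0`, `class_shift_sd=0`, uniform fiber composition) drops
the call rate below 1%.

The same stages are scriptable from the shell:

```
muscletx simulate --config cfg.yaml --out-dir sim/
muscletx de --counts sim/counts.tsv --metadata sim/metadata.tsv \
            --annotation sim/annotation.tsv --out de.tsv
muscletx cluster --counts ... --out-newick tree.nwk
muscletx junctions --junctions sim/junctions.tsv \
            --annotation sim/annotation.tsv --out-bed novel.bed
```

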