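# Methods

This note documents the statistical models behind `muscletx`, the
parameters that matter, the design decisions taken where several
defensible choices existed, and what the synthetic-data tests do and do
not demonstrate about real data.

## Normalization

Expression is quantified as FPKM over unique reads,
`FPKM_ij = 10^9 · c_ij / (l_i · N_j)`, with transcript length `l_i` in
bp taken from the annotation as authoritative (no recomputation from
exon structure, though the two are validated to agree when exons are
supplied). The per-sample depth `N_j` sums counts over nuclear
transcripts only. Muscles differ several-fold in mitochondrial content;
if mitochondrial reads stayed in the denominator, every nuclear
transcript in a mitochondria-rich muscle would appear spuriously
down-regulated. Mitochondrial transcripts still receive FPKM values —
only their contribution to the depth is removed. A consequence worth
knowing: `Σ_i FPKM_ij · l_i(kb)` equals `10^6 · total/nuclear` reads
per sample, i.e. exceeds 10^6 in proportion to mitochondrial load.

All log-scale computation uses `log2(FPKM + 1)`. A single pseudocount
convention is used everywhere (ANOVA input, PCA input, tissue-mean
profiles, cross-species comparison) rather than per-stage variants; it
maps FPKM 0 to 0 and compresses only the sub-FPKM-1 range that the
expression filter removes from most analyses anyway.

## Differential expression

Per transcript, a fixed-effects one-way ANOVA across the tissues of
the analysed subset on log expression; q-values by Benjamini–Hochberg
over exactly the tested transcript set (per analysis, not pooled
across analyses). The tested set is pre-filtered to transcripts with
mean FPKM > 1 (strict) in at least one subset tissue. The fold-change
filter is computed on raw-FPKM tissue means as
`(max + ε)/(min + ε)` with ε = 0.1 — the max/min convention is the
only single-number fold change consistent across >2 groups, and the
pseudocount tames zero means while staying small against the FPKM > 1
filter. Degenerate inputs follow deterministic rules: all groups
identical ⇒ F = 0, p = 1; between-group signal with zero within-group
variance ⇒ p reported as 1e-300. The two-group case is algebraically
the pooled-variance t-test (F = t²), which the tests verify
numerically.

BH is implemented directly as the tail minimum
`q_(i) = min_{j≥i} p_(j)·m/j` (reverse cumulative minimum of
`p·m/rank`), because the package's contract is exact agreement with
that definition; an independent brute-force oracle and
`statsmodels.multipletests` corroborate it in the tests.

## Similarity structure

Tissue profiles are tissue-mean log expression over expressed
transcripts (expressed-only by default; an all-transcripts flag
exists). Distances are Euclidean; clustering is complete-linkage
agglomeration implemented directly so that tie-breaking is fully
deterministic: equal merge heights are resolved by the lexicographically
smallest pair of cluster labels, making the newick string a pure
function of the input. Newick branch lengths place each internal node
at half its merge height (a two-leaf tree merged at height 5 renders
as `(A:2.5,B:2.5);`). Row Z-scores use the sample (n−1) standard
deviation; constant rows become all-zero and are flagged rather than
propagating NaNs into heat maps.

## Principal-axis analysis

PCA treats samples as observations and transcripts as features,
centering each transcript but not scaling it — abundant transcripts
are allowed to dominate, which is what makes PC1 interpretable as the
fast/slow program rather than a whitened abstraction. Components are
sign-canonicalized (largest-|loading| entry positive). Per-transcript
association with a component is the Pearson correlation between the
transcript's per-sample expression and the score vector; R² = r².
Constant transcripts report missing.

Sampling variability uses a stratified bootstrap: replicate samples
are resampled with replacement *within* tissue, preserving the design;
tissues with a single replicate cannot be resampled and are excluded
with a warning. Intervals are percentile intervals (default 99%,
10,000 replicates by default; tests and the acceptance script use 500
to keep runtimes in seconds), with each bootstrap component sign-aligned
to the point estimate before aggregation. An analytic Fisher-z interval
is provided as an optional alternative for single correlations.

## Fiber type

Fiber composition is proxied by the share of Myh-aligned reads on each
*Myh* transcript per tissue (replicates pooled). The default basis is
raw read counts; because read-level proportions are length-biased, an
FPKM basis is offered and the basis used is recorded in the output.
Marker analyses correlate tissue-mean log expression of a candidate
gene with a reference (*Myh4* for fast markers, *Myh7* for slow) across
tissues — one point per tissue — and summarise a panel by its median R²
and the count above 0.5.

## Specificity and overlays

The tissue-specificity statistic is the tau index over per-tissue mean
FPKM, `tau = Σ_i (1 − x_i/x_max)/(n−1)`: 0 for uniform expression, 1
for single-tissue exclusivity, scale-invariant, and monotone under
moving expression mass toward the top tissue. The fraction of total
expression in the top tissue is reported alongside as a simpler
alternative; both are labelled in output. Gene-list overlays intersect
upper-cased symbols; disease, drug-target and secreted lists are
user-supplied files, never live database queries. Myokine candidates
are secreted genes significantly DE among skeletal tissues with a
maximum tissue-mean FPKM above 10.

## Cross-species comparison

Ortholog tables are inputs, reduced to strict one-to-one pairings
(ambiguous rows dropped and counted). Expression is compared on
log2(FPKM+1) tissue means with no cross-species renormalization.
Shared DE uses each species' own q-values (default q < 0.05, fold
change > 2 for the two-tissue contrast); direction concordance is
sign agreement of the signed log2 fold changes, with zero fold change
discordant unless both are zero. Sex differences reuse the standard
two-group machinery with male/female replicate groups as the two
"tissues".

## Junction discovery

Known introns are the gaps between consecutive exons of every
annotated transcript. Observed junctions (normalized to 0-based
half-open coordinates on read, with the input dialect declared per
file and double conversion a hard error) are aggregated across
samples, known introns removed, and the rest ranked by total read
support. Classification: both ends on annotated exon boundaries with
at least one exon strictly inside ⇒ exon skipping; one or both ends
off any boundary ⇒ novel exon/site candidate; boundary-consistent with
nothing skipped, or an unannotated chromosome ⇒ unresolved. Matching
is strand-aware with an agnostic fallback since junction files vary.
The default support floor is 1 read; ≥5 is a sensible floor when
curating candidates by hand.

## Synthetic data

The generator draws counts `NegBin(mean = μ_it · l_i(kb) · depth/10^6,
variance = m + φm²)` with dispersion φ = 0.05 by default — a standard
bulk RNA-seq overdispersion level — over log-normal baselines
(log2 μ ~ N(3, 2), FPKM-like units). Structure is layered on top:

* per-transcript class-level shifts (SD 0.7) separating
  skeletal/cardiac/smooth, plus small per-tissue shifts (SD 0.15);
* a latent per-tissue fast-twitch fraction (soleus 0.03 … EDL 0.92)
  that partitions a fixed Myh budget between MYH7 (slow) and
  MYH2/1/4 (fast) and drives designated axis genes,
  `log2 μ = a + b·f + noise`, with the noise SD solved from the target
  R² so correlations land where intended in expectation;
* planted DE: a configured fraction of transcripts shifted by
  ±log2(fold change) in a random non-trivial tissue subset. DE is
  planted only on transcripts with baseline FPKM ≥ 4 so that planted
  truth is visible to the FPKM > 1 expression filter — the DE rates
  the pipeline reports are rates among expressed transcripts;
* mitochondrial transcripts (13, matching the mtDNA mRNA complement)
  rescaled per tissue so the mitochondrial read share lands at a value
  drawn from the configured range;
* optional sex-biased transcripts shifted in male samples.

Defaults emulate the scale of a multi-muscle mouse atlas — 16 tissues
(11 skeletal, 2 cardiac, 3 smooth) × 6 replicates — at 2,000
transcripts and a nominal depth of 2×10^6, a deliberate scale-down
that keeps every simulation in the test suite in the seconds range
while preserving per-transcript counting statistics (typical mean
counts in the tens).

The two-species generator shares a baseline between species, adds
log-normal divergence (total SD 1.45, giving ortholog R² ≈ 0.6 against
the baseline spread of 2.0), and plants an EDL-vs-soleus contrast in
200 shared orthologs. Concordance is assigned by deterministic quota —
exactly round(concordance·n) genes share sign — rather than per-gene
coin flips, so the expected concordance is exact, not binomial.
Mitochondrial load is held constant across the two tissues within each
species, and DE is never planted on mitochondrial transcripts, so the
planted contrast is the only shared between-tissue signal.

All randomness flows from a mandatory seed through one
`numpy.random.Generator`; identical configs produce byte-identical
datasets. Everything planted is returned in a truth object (including
the exact per-tissue expression means), so analytic expectations are
recomputable from truth plus config.

What the generator does *not* emulate: GC/length bias, batch effects,
library-preparation artifacts, isoform switching within genes,
read-level errors, and correlated gene programs beyond the single
fast/slow axis. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to the
full messiness of real libraries.

## Test and acceptance-run problem sizes

Null FDR and power checks use 2,000 transcripts × 11 tissues × 6
replicates (20 and 10 seeds respectively in the test suite; 5 in the
acceptance script). Clustering recovery uses 1,000 transcripts × 16
tissues with class shifts of SD 2.0 (≈6× the within-tissue log-scale
noise SD). The rank-1 axis check uses a 250-transcript design with 150
drivers at target R² 0.998 and dispersion 0.001, where PC1 should carry
≥95% of variance. Bootstrap coverage uses a Gaussian spike model (40
features, 20 tissues × 6 replicates) whose population PC1 variance
fraction is known in closed form. Junction discovery plants 50 novel
events among the ~7,000 introns of a 2,000-transcript annotation.

## Known limitations

* The ANOVA assumes homoscedastic Gaussian residuals on the log scale;
  NB counts satisfy this only approximately, which is visible as
  slightly conservative null behaviour at low counts.
* No moderated/shrinkage variance estimation (limma/DESeq style) —
  deliberately, as the pipeline mirrors a classical ANOVA workflow.
* Fold changes on raw-FPKM means depend mildly on the ε = 0.1
  pseudocount for transcripts near zero in some tissue.
* The complete-linkage implementation is O(n³) and intended for tissue
  counts (tens), not for clustering transcripts.
* Percentile bootstrap intervals undercover slightly for variance
  fractions at small sample counts; the coverage test documents the
  regime (≥100 samples) where the 99% interval is reliable.
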