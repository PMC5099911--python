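# Methods

This note documents the models, conventions, parameter defaults and
design choices behind `linc_chin`, and what the synthetic benchmark
does and does not demonstrate.

## Coordinates and region algebra

All internal coordinates are 0-based half-open (BED convention); GTF
(1-based closed) and GWAS SNP positions (1-based) are converted at the
reader boundary. Overlap means ≥ 1 shared base:
`a.start < b.end and b.start < a.end` on the same chromosome, strand
ignored. Anchor merging uses `max_gap = 0` by default — only
overlapping or directly book-ended anchors join, the most conservative
reading of "overlapping, neighboring"; the gap is a config knob.
Windows are clipped at chromosome bounds (chromosome sizes are a
required input). Mixed chromosome-name dialects ("chr1" vs "1") across
inputs are a hard error rather than a silent normalization.

## Network model

The ChIN is a simple weighted graph: parallel interaction clusters
between one node pair collapse into a single edge carrying
`weight` (cluster count) and `total_pet`; clusters whose two anchors
fall inside one merged node would be self-loops and are dropped (and
logged). Promoter windows are symmetric ±2.5 kb around each distinct
TSS — symmetric windows make strand irrelevant to window shape, so
strand only decides which coordinate is a TSS. A node may carry several
genes when promoter windows overlap; gene-level views (the
lincRNA–mRNA subnetwork, k-hop target sets) therefore expand node
edges to all gene pairs and report distinct-partner counts, which is
kept separate from raw node degree.

The scale-freeness descriptor fits the discrete power law
P(k) ∝ k^−α by maximum likelihood (zeta-function normalizer, α
bounded in (1.01, 8)), selecting xmin by minimizing the KS distance
between the empirical tail and the fitted model. A degenerate degree
distribution (fewer than two distinct values) reports no exponent.
Community detection is weighted Louvain modularity optimization with a
fixed seed and labels ordered by smallest member node id; the original
analysis tool for overlapping communities is intentionally not
reproduced, since only community membership and size feed downstream
(enrichment runs on communities with ≥ 20 nodes). Canonical TSS for
gene-pair distances is the 5′-most TSS on the gene's strand.

## Classification rules

The C1–C5 cascade is deterministic and exhaustive: protein-coding
partner → C1; else any other annotated partner gene → C2; else any
edge (necessarily to pure-DRE nodes) → C3; else an RNAPII peak
(called peaks, not a coverage threshold) overlapping a promoter window
→ C4; else C5. "Not transcribed" is recorded as evidence
(max RPKM = 0) but the cascade itself keys on interactions and peaks
only, so the partition is input-complete.

Promoter state uses the 2-kb means: label = enhancer-like iff
log2((me1 + ε)/(me3 + ε)) > 0; an exact tie or an undefined ratio
(both means zero at ε = 0) is promoter-like, with the undefined case
flagged. Bins run left-to-right in genome coordinates (not
strand-flipped): the windows are symmetric and the deciding statistic
is orientation-free. ε defaults to 0.01 coverage/RPKM units wherever a
ratio or fold change could divide by zero; the label is invariant
under common positive rescaling of both tracks when ε is scaled
alongside.

Binding-site classes follow the precedence: CTCF-anchor overlap with
cohesin co-binding → TAD/sub-TAD; else RNAPII-anchor overlap →
transcriptional; else other. Cell-exclusive expression compares the
maximum RPKM over the target cell's samples (all subcellular
fractions) against the maximum elsewhere,
FC = (max_target + ε)/(max_other + ε), specific at FC ≥ 2.

DRE chromatin-state labels resolve multi-overlaps by a fixed priority
(strong enhancer > weak enhancer > transition/elongation > weak
transcribed > insulator > polycomb-repressed >
heterochromatin/repetitive); raw segmentation names map to this
vocabulary through an explicit two-column table — no substring
guessing — and unmapped names are an error. States mapped to "others"
(e.g. ChromHMM promoter states) do not compete in the priority order.

## Statistics

**Permutation colocalization.** Statistic: number of query regions
overlapping ≥ 1 reference region (the reference set is merged first).
Null: each query region relocated uniformly at random on its own
chromosome with length preserved (a genome-wide mode exists);
p = (1 + #{perm ≥ obs})/(1 + N), z = (obs − mean)/sd with sd = 0
flagged rather than inverted. The implementation is vectorized over
permutations (searchsorted against merged reference ends), which is
what lets the calibration experiment (500 replicates × 200
permutations × 1000 regions) run in seconds. Assembly-gap masking is
out of scope for synthetic genomes. Calibration experiments use sets
of 1000 × 1 kb regions on a 2 × 20 Mb genome: with much smaller sets
the integer overlap count is so discrete that tied permutation values
make the empirical p visibly conservative, which says nothing about
the test and everything about granularity; at these sizes the p-value
distribution under the null is indistinguishable from uniform.

**Correlation and ranking.** Pearson on log2(RPKM+1) by default
(Spearman available); zero-variance vectors give a flagged NaN. The
0.6 "highly correlated" threshold is a fixed parameter. Ranked lists
break score ties lexicographically by gene id so every downstream step
is deterministic.

**Preranked GSEA.** ES is the maximum deviation from zero of the
weighted KS running sum (hit increments ∝ |score|^p, default p = 1,
falling back to uniform when all hit scores are zero; miss decrements
uniform). Null: gene-label permutation (random same-size hit sets) —
a phenotype-permutation null does not exist here because each lincRNA
has exactly one ranking. NES = ES / mean(|null ES| of the same sign);
p is the same-sign empirical tail; FDR is Benjamini–Hochberg across
terms, which is simpler and exactly reproducible compared to the
signed-NES FDR of the original GSEA procedure. GSEA uses its own
permutation depth (default 2000) because the smallest attainable
empirical p, 1/(N+1), must sit below the 0.01 FDR threshold after BH
correction over the term list; the generic `n_perm` (default 1000)
applies to the colocalization tests. Sets with fewer than 5 members in
the list are skipped; a set equal to the whole universe is an error
(the miss decrement is undefined).

**Association matrix.** Entries are sign(NES) · min(−log10 q, 4) for
terms with q ≤ 0.01, zero otherwise; rows (lincRNAs) and columns
(terms) are clustered separately by k-means (k = 10, 10 restarts,
fixed seed). The matrix orientation is fixed as lincRNAs = rows.

**Community enrichment** is the one-sided hypergeometric tail
P(X ≥ k) with BH FDR across terms; group comparisons are two-sided
Wilcoxon rank-sum with normal approximation and tie correction.

## Synthetic data

The generator plants every truth the pipeline is supposed to recover
and writes it to `manifest.json`; the test suite enumerates the
manifest's fields and fails if any planted attribute is unasserted.

Desk preset: 2 chromosomes × 1 Mb, 200 genes (60% protein-coding,
25% lincRNA, 10% antisense, 5% miRNA) in fixed 10-kb slots — gene body
at slot+3000..slot+5000, DRE zone at slot+8000..slot+9500 — so
promoter windows, extended genic regions and DRE anchors never cross
slot boundaries. This makes merged nodes carry exactly one gene and
planted interaction categories exactly recoverable; it is a deliberate
idealization (real promoter windows do overlap neighboring genes).
Planted categories default to C1:15, C2:8, C3:7, C4:8, C5:12 — the
real annotation is far more C5-heavy (most lincRNAs are silent in any
one cell line), but a desk-scale network needs enough interacting
lincRNAs to exercise the downstream stages. Additional
promoter–promoter scaffold edges among protein-coding genes follow a
power-law degree target (exponent 2.5).

Noise models are the simplest that make the thresholds non-trivial:
Poisson per-100-bp coverage bins (dominant mark at snr × base rate,
base rate 5), log-normal RPKM (log2 sd 1.0) with planted pair
correlations implemented as one latent sample factor per lincRNA
(partners conditionally independent given it), an all-zero stratum for
C5 lincRNAs, and a forced ≥ 4× target-cell maximum for planted
cell-exclusive genes. Cell-exclusive genes are drawn from C2/C3
lincRNAs because the specificity forcing would otherwise overwrite the
planted correlation structure of C1 rows. The focus lincRNA
additionally gets an 8-gene co-expression module (r = 0.75) with a
matching gene set, so guilt-by-association has a recoverable positive
control. CHART-style peaks land in each k-hop neighborhood region with
probability min(1, 0.1 × enrichment_factor) over a uniform background;
the expression panel is 108 samples over 55 cell types with cycling
subcellular-fraction labels.

What passing tests therefore show: the algorithms are correct on their
own contracts (oracle equivalences), calibrated (permutation type-I
error), and able to recover planted signal at realistic
signal-to-noise. What they do not show: performance on ENCODE-scale
data, robustness to overlapping promoters, unmappable regions, copy
number, batch effects, or annotation errors — none of which the
generator emulates. Published cell-line figures (gene counts,
percentages) depend on full-scale inputs and are not reproduced at
desk scale.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| promoter half-width | 2500 bp | TSS window ± half-width |
| genic flank | 2500 bp | extended gene body for binding/SNP overlap |
| merge max_gap | 0 bp | anchor-merge gap tolerance |
| hop k | 3 | ChIN neighborhood depth for target calls |
| ε | 0.01 | pseudocount for ratios/fold changes |
| correlation threshold | 0.6 | "highly correlated" cutoff |
| specificity fold change | 2.0 | cell-exclusive expression cutoff |
| GSEA FDR | 0.01 | significance for function assignment |
| community min size | 20 | enrichment size floor |
| n_perm / gsea_n_perm | 1000 / 2000 | permutation depths |

## Determinism

Every stochastic operation takes an explicit seed and records it in
its outputs; the generator derives sequential child seeds from one
root seed, and two runs of the full pipeline with the same seed
produce byte-identical text outputs (this is tested). Known
limitations: the permutation null ignores mappability and GC;
inter-chromosomal interactions are retained in the graph but excluded
from distance summaries; profiles use the canonical TSS only (other
TSS windows can be emitted with a flag); the Louvain substitution
means community boundaries need not match overlapping-community
methods on the same graph.
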