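# linc-chin

Chromatin interaction network (ChIN) analysis of lincRNA
transcriptional regulation.

Long intergenic noncoding RNAs (lincRNAs) are transcribed outside
protein-coding loci, and most have no annotated function. Because
RNAPII-mediated ChIA-PET captures which genomic regions are in physical
contact during transcription, the looping structure around a lincRNA
locus is itself evidence about what the lincRNA does: which promoters
it shares a transcription factory with, which distal regulatory
elements (DREs) feed it, whether its own promoter chromatin looks like
an enhancer, and which genes its transcript can reach in local nuclear
space. This package implements that analysis as a tested pipeline for
computational genomicists: from interaction clusters and a GENCODE-style
annotation to networks, lincRNA classifications, function assignment and
GWAS-SNP target mapping — with a seeded synthetic-data generator that
emulates every input at desk scale and records the planted ground truth.

## The analysis

**Network construction.** ChIA-PET interaction clusters contribute two
anchor regions each; overlapping or book-ended anchors are merged into
nodes, and each cluster adds an edge between the nodes containing its
anchors (weight = supporting clusters, `total_pet` = summed paired-end
tags). A node is a *promoter node* when it overlaps a ±2.5 kb TSS window
by ≥ 1 bp, otherwise a *DRE*. Descriptors include the degree
distribution with a discrete maximum-likelihood power-law fit
(P(k) ∝ k^−α, xmin chosen by KS minimization), k-cores, transitivity,
density, centralities, and Louvain communities.

**LincRNA interaction categories.** Each lincRNA gets exactly one of
C1 (edge to a node carrying a protein-coding gene), C2 (edge to a node
carrying another annotated gene), C3 (edges only to DREs), C4 (no
edges, but RNAPII peaks in the promoter), C5 (neither).

**Promoter chromatin state.** Over ±1 kb of the TSS,
log2((H3K4me1 + ε)/(H3K4me3 + ε)) > 0 calls the promoter
*enhancer-like*, otherwise *promoter-like*; ±2.5 kb windows are also
profiled in 20 bins.

**Statistics.** Colocalization of two region sets is tested by a
permutation null that relocates each query region uniformly on its own
chromosome, preserving length; reported as observed count, null
mean/sd, z-score and empirical p = (1 + #{perm ≥ obs})/(1 + N).
Guilt-by-association ranks protein-coding genes by Pearson correlation
with the lincRNA on log2(RPKM+1) and runs preranked GSEA (weighted-KS
enrichment score, gene-label permutation null, BH FDR). Community
enrichment is a one-sided hypergeometric test; group contrasts use the
Wilcoxon rank-sum test.

**RNA-level targets.** Genes within k = 3 ChIN hops of the lincRNA's
promoter node are *interacting*; genes whose ±2.5 kb extended body
overlaps a CHART/ChIRP binding peak are *bound*; the
bound∩interacting / bound-only / interacting-only partition and the
binding-in-neighborhood permutation z quantify how much genome
organization explains the binding profile. GWAS SNPs inside lincRNA
loci (or DREs contacting lincRNA promoters) inherit the genes on
adjacent promoter nodes as candidate targets.

## Worked example

The numbered scripts under `analysis/` run the full story on the
synthetic bundle (regenerated automatically under `results/synthetic/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_build_network.py --seed 1
python analysis/04_classify_lincrnas.py --seed 1
python analysis/05_assign_functions.py --seed 1
```

prints, among other lines:

```
ChIN: 184 nodes (157 promoter, 27 DRE), 169 edges
  degree distribution power-law exponent 3.11 (xmin=2)
  lincRNAs with a promoter node in the ChIN: 30
lincRNA interaction categories: {'C1': 15, 'C2': 8, 'C3': 7, 'C4': 8, 'C5': 12}
  planted-category recovery: 50/50
enhancer-like lincRNA promoters: 18/50 (36.0%)
  planted-label recovery: 170/170
GSEA: 15 C1 lincRNAs x 13 gene sets; 1 significant at FDR <= 0.01
  top term for LINC0014: GO_FOCUS_MODULE (ES=1.00, NES=1.80, q=0.008115; planted module: True)
```

Read: of 50 annotated lincRNAs, 30 have a promoter node in the ChIN and
the interaction-category cascade recovers every planted label; 36% of
lincRNA promoters are H3K4me1-dominant (enhancer-like); and
guilt-by-association recovers exactly the co-expression module planted
for the focus lincRNA. `analysis/06_predict_rna_targets.py` and
`analysis/07_map_gwas_snps.py` continue with RNA-level target calls
(binding-in-neighborhood z ≈ 29 for the planted enrichment) and
SNP-to-target mapping (every planted SNP reaches its partner gene).

The same pipeline is scriptable end to end:

```sh
linc-chin simulate --preset desk --seed 1 --outdir inputs/
linc-chin run-all --indir inputs/ --outdir out/
```

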