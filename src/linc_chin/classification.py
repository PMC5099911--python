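"""LincRNA classification.

Four classifiers live here:

* interaction categories C1-C5 from ChIN edges and RNAPII promoter
  peaks (C1 contacts protein-coding genes, C2 contacts other annotated
  genes, C3 contacts only DREs, C4 has RNAPII promoter peaks but no
  contacts, C5 has neither);
* enhancer-like vs promoter-like promoters from the
  log2(H3K4me1/H3K4me3) ratio over +/- 1 kb of the TSS;
* RNA binding-site classes from participation in CTCF- vs
  RNAPII-mediated interactions;
* cell-exclusive expression from a max-over-samples fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import CoverageTrack, GenomicInterval, make_window
from .io import ExpressionMatrix, GeneRecord
from .network import ChIN
from .annotation import promoter_windows

logger = logging.getLogger(__name__)

CATEGORIES = ("C1", "C2", "C3", "C4", "C5")


@dataclass
class CategoryEvidence:
    n_coding_partners: int = 0
    n_noncoding_partners: int = 0
    n_dre_partners: int = 0
    n_rnapii_promoter_peaks: int = 0
    max_rpkm: float = float("nan")


@dataclass
class CategoryAssignment:
    categories: dict[str, str]  # gene_id -> C1..C5
    evidence: dict[str, CategoryEvidence]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for c in self.categories.values():
            out[c] += 1
        return out


def classify_categories(
    lincrnas: Sequence[GeneRecord],
    chin: ChIN,
    genes: Mapping[str, GeneRecord],
    rnapii_peaks: Sequence[GenomicInterval],
    expression: ExpressionMatrix | None = None,
    half_width: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CategoryAssignment:
    """Assign every lincRNA to exactly one interaction category.

    Decision cascade: an edge to a node carrying a protein-coding gene
    -> C1; else an edge to a node carrying any other annotated gene ->
    C2; else any edge (necessarily to pure-DRE nodes) -> C3; else an
    RNAPII peak overlapping a promoter window by >= 1 bp -> C4; else C5.
    """
    peak_trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(rnapii_peaks):
        peak_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)

    categories: dict[str, str] = {}
    evidence: dict[str, CategoryEvidence] = {}
    for lnc in lincrnas:
        if lnc.gene_id not in genes:
            raise KeyError(f"lincRNA {lnc.gene_id} absent from the annotation")
        ev = CategoryEvidence()
        if expression is not None and lnc.gene_id in expression.values.index:
            ev.max_rpkm = float(expression.gene_values(lnc.gene_id).max())

        coding: set[str] = set()
        noncoding: set[str] = set()
        dre_partners: set[int] = set()
        for node in chin.nodes_of_gene(lnc.gene_id):
            for nb in chin.neighbors(node):
                partner_genes = [g for g in chin.genes_on_node(nb)
                                 if g in genes and g != lnc.gene_id]
                if not partner_genes:
                    dre_partners.add(nb)
                for g in partner_genes:
                    if genes[g].biotype == "protein_coding":
                        coding.add(g)
                    else:
                        noncoding.add(g)
        ev.n_coding_partners = len(coding)
        ev.n_noncoding_partners = len(noncoding)
        ev.n_dre_partners = len(dre_partners)

        n_peaks = 0
        for w in promoter_windows(lnc, half_width, chrom_sizes):
            tree = peak_trees.get(w.chrom)
            if tree is not None:
                n_peaks += len(tree.overlap(w.start, w.end))
        ev.n_rnapii_promoter_peaks = n_peaks

        if coding:
            cat = "C1"
        elif noncoding:
            cat = "C2"
        elif dre_partners:
            cat = "C3"
        elif n_peaks > 0:
            cat = "C4"
        else:
            cat = "C5"
        categories[lnc.gene_id] = cat
        evidence[lnc.gene_id] = ev
    return CategoryAssignment(categories, evidence)


# ---------------------------------------------------------------------------
# Promoter chromatin-state profile


@dataclass
class PromoterProfile:
    gene_id: str
    tss: int
    me1_bins: tuple[float, ...]
    me3_bins: tuple[float, ...]
    me1_2kb: float
    me3_2kb: float
    log2_ratio: float
    label: str  # "enhancer_like" | "promoter_like"
    ratio_defined: bool = True


def profile_promoter(
    gene: GeneRecord,
    me1_track: CoverageTrack,
    me3_track: CoverageTrack,
    epsilon: float = 0.01,
    half_width: int = 2500,
    inner_half_width: int = 1000,
    n_bins: int = 20,
    tss: int | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PromoterProfile:
    """Binned H3K4me1/H3K4me3 profile and enhancer/promoter-like label.

    Bins run left-to-right in genome coordinates over the +/- half_width
    window around the canonical TSS (or an explicit one).  The label is
    the sign of log2((me1 + eps)/(me3 + eps)) over the inner +/- 1 kb
    window: strictly positive -> enhancer_like, otherwise promoter_like.
    """
    if tss is None:
        tss = gene.canonical_tss
    window = make_window(gene.chrom, tss, half_width, chrom_sizes)
    edges = np.linspace(window.start, window.end, n_bins + 1).round().astype(int)

    def binned(track: CoverageTrack) -> tuple[float, ...]:
        return tuple(
            track.mean(GenomicInterval(window.chrom, int(s), int(e)))
            for s, e in zip(edges[:-1], edges[1:])
        )

    inner = make_window(gene.chrom, tss, inner_half_width, chrom_sizes)
    me1_2kb = me1_track.mean(inner)
    me3_2kb = me3_track.mean(inner)
    ratio_defined = me1_2kb + epsilon > 0 and me3_2kb + epsilon > 0
    if ratio_defined:
        log2_ratio = math.log2((me1_2kb + epsilon) / (me3_2kb + epsilon))
    else:
        log2_ratio = float("nan")
    label = "enhancer_like" if ratio_defined and log2_ratio > 0 else "promoter_like"
    return PromoterProfile(
        gene_id=gene.gene_id,
        tss=tss,
        me1_bins=binned(me1_track),
        me3_bins=binned(me3_track),
        me1_2kb=me1_2kb,
        me3_2kb=me3_2kb,
        log2_ratio=log2_ratio,
        label=label,
        ratio_defined=ratio_defined,
    )


# ---------------------------------------------------------------------------
# Binding-site interaction classes


@dataclass(frozen=True)
class BindingSiteClass:
    peak: GenomicInterval
    site_class: str  # "tad_subtad" | "rnapii_transcriptional" | "other"


def _anchor_tree(chin: ChIN) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for node_id, node in chin.nodes.items():
        trees.setdefault(node.region.chrom, IntervalTree()).addi(
            node.region.start, node.region.end, node_id
        )
    return trees


def classify_binding_sites(
    peaks: Sequence[GenomicInterval],
    ctcf_chin: ChIN,
    cohesin_peaks: Sequence[GenomicInterval],
    rnapii_chin: ChIN,
) -> list[BindingSiteClass]:
    """Classify RNA binding peaks by the interactions they participate in.

    Precedence: a peak on a CTCF-interaction anchor that is co-bound by
    cohesin -> tad_subtad; else a peak on an RNAPII-interaction anchor
    -> rnapii_transcriptional; else other.
    """
    ctcf_trees = _anchor_tree(ctcf_chin)
    rnapii_trees = _anchor_tree(rnapii_chin)
    cohesin_trees: dict[str, IntervalTree] = {}
    for p in cohesin_peaks:
        cohesin_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    out = []
    for peak in peaks:
        ctree = ctcf_trees.get(peak.chrom)
        ctcf_hits = ctree.overlap(peak.start, peak.end) if ctree is not None else set()
        cohesin_bound = False
        if ctcf_hits:
            cotree = cohesin_trees.get(peak.chrom)
            if cotree is not None:
                for hit in ctcf_hits:
                    if cotree.overlap(hit.begin, hit.end):
                        cohesin_bound = True
                        break
        if ctcf_hits and cohesin_bound:
            cls = "tad_subtad"
        else:
            rtree = rnapii_trees.get(peak.chrom)
            if rtree is not None and rtree.overlap(peak.start, peak.end):
                cls = "rnapii_transcriptional"
            else:
                cls = "other"
        out.append(BindingSiteClass(peak, cls))
    return out


# ---------------------------------------------------------------------------
# Cell-exclusive expression


@dataclass
class SpecificityResult:
    gene_id: str
    target_cell: str
    max_target: float
    max_elsewhere: float
    fold_change: float
    is_specific: bool


def cell_specificity(
    expression: ExpressionMatrix,
    gene_id: str,
    target_cell: str,
    epsilon: float = 0.01,
    fold_threshold: float = 2.0,
) -> SpecificityResult:
    """Cell-exclusive expression by max-over-samples fold change.

    fold_change = (max RPKM over the target cell's samples + eps) /
    (max over all other samples + eps); the gene is called specific
    when fold_change >= fold_threshold (default 2).
    """
    values = expression.gene_values(gene_id)
    target_samples = expression.samples_for_cell(target_cell)
    if not target_samples:
        raise ValueError(f"no samples for cell type {target_cell!r}")
    other_samples = [s for s in expression.samples if s not in set(target_samples)]
    if not other_samples:
        raise ValueError("no non-target samples to compare against")
    max_target = float(values[target_samples].max())
    max_elsewhere = float(values[other_samples].max())
    fc = (max_target + epsilon) / (max_elsewhere + epsilon)
    return SpecificityResult(
        gene_id, target_cell, max_target, max_elsewhere, fc, fc >= fold_threshold
    )
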