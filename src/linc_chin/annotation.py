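"""Region derivation and element annotation.

Promoter windows (+/- 2.5 kb of each TSS) and genic regions (+/- 2.5 kb
of the gene body) are the two region classes everything downstream
keys on.  DREs pick up chromatin-state labels from a ChromHMM-style
segmentation under a fixed priority order, super-enhancers are joined
to DREs by overlap, and GWAS SNPs are mapped to direct and
interaction-inferred target genes through the ChIN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, clip_interval, make_window
from .io import GeneRecord, SNPRecord
from .network import ChIN

logger = logging.getLogger(__name__)

#: Chromatin-state vocabulary in priority order (rank 1 = highest).
#: A DRE overlapping several states gets the highest-priority one;
#: a DRE overlapping none of the listed states is "others".
STATE_PRIORITY: tuple[str, ...] = (
    "strong_enhancer",
    "weak_enhancer",
    "txn_transition_elongation",
    "weak_transcribed",
    "insulator",
    "polycomb_repressed",
    "heterochromatin_repetitive",
    "others",
)

STATE_RANK: dict[str, int] = {s: i + 1 for i, s in enumerate(STATE_PRIORITY)}


def promoter_windows(
    gene: GeneRecord,
    half_width: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """One symmetric window [TSS - hw, TSS + hw) per distinct TSS, clipped.

    The window is strand-independent by symmetry; strand only selected
    which positions are TSSs in the first place.
    """
    out = []
    for tss in sorted(set(gene.tss_list)):
        out.append(make_window(gene.chrom, tss, half_width, chrom_sizes))
    return out


def genic_region(
    gene: GeneRecord,
    flank: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """The extended gene body: [body.start - flank, body.end + flank), clipped."""
    iv = GenomicInterval(
        gene.chrom, max(0, gene.body.start - flank), gene.body.end + flank
    )
    clipped = clip_interval(iv, chrom_sizes)
    assert clipped is not None
    return clipped


def label_dre_states(
    dres: Mapping[int, GenomicInterval],
    segmentation: Sequence[tuple[GenomicInterval, str]],
    state_mapping: Mapping[str, str],
) -> dict[int, str]:
    """Assign each DRE the highest-priority chromatin state it overlaps.

    ``state_mapping`` translates raw segmentation labels into the fixed
    vocabulary; raw labels without a mapping are a hard error.  Raw
    labels mapped to "others" (e.g. ChromHMM promoter states) do not
    compete in the priority order — a DRE overlapping only those is
    "others", same as a DRE overlapping nothing.
    """
    unmapped = sorted({lab for _, lab in segmentation} - set(state_mapping))
    if unmapped:
        raise ValueError(f"segmentation states without a vocabulary mapping: {unmapped}")
    bad = sorted({v for v in state_mapping.values()} - set(STATE_PRIORITY))
    if bad:
        raise ValueError(f"state mapping targets outside the vocabulary: {bad}")

    trees: dict[str, IntervalTree] = {}
    for iv, raw in segmentation:
        vocab = state_mapping[raw]
        if vocab == "others":
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, vocab)

    labels: dict[int, str] = {}
    for dre_id, region in dres.items():
        tree = trees.get(region.chrom)
        hits = tree.overlap(region.start, region.end) if tree is not None else ()
        states = {h.data for h in hits}
        if states:
            labels[dre_id] = min(states, key=lambda s: STATE_RANK[s])
        else:
            labels[dre_id] = "others"
    return labels


def super_enhancer_overlap(
    dres: Mapping[int, GenomicInterval],
    super_enhancers: Sequence[GenomicInterval],
) -> dict[int, list[int]]:
    """Map each super-enhancer (by list index) to the DRE ids it overlaps."""
    tree_by_chrom: dict[str, IntervalTree] = {}
    for dre_id, region in dres.items():
        tree_by_chrom.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, dre_id
        )
    out: dict[int, list[int]] = {}
    for i, se in enumerate(super_enhancers):
        tree = tree_by_chrom.get(se.chrom)
        hits = tree.overlap(se.start, se.end) if tree is not None else ()
        if hits:
            out[i] = sorted(h.data for h in hits)
    return out


def se_linked_lincrnas(
    chin: ChIN,
    genes: Mapping[str, GeneRecord],
    super_enhancers: Sequence[GenomicInterval],
) -> set[str]:
    """LincRNAs whose promoter node contacts a DRE overlapping a super-enhancer."""
    dres = {i: chin.node_region(i) for i in chin.dre_nodes()}
    se_map = super_enhancer_overlap(dres, super_enhancers)
    se_dres: set[int] = set()
    for dre_ids in se_map.values():
        se_dres.update(dre_ids)
    linked: set[str] = set()
    for gene_id, gene in genes.items():
        if gene.biotype != "lincRNA":
            continue
        for node in chin.nodes_of_gene(gene_id):
            if any(nb in se_dres for nb in chin.neighbors(node)):
                linked.add(gene_id)
                break
    return linked


@dataclass
class SNPTargets:
    rsid: str
    trait: str
    direct_genes: list[str]
    inferred_targets: list[str]
    via: list[str]  # "lincRNA:<id>" or "dre:<node_id>" hit regions


def map_snps_to_targets(
    snps: Sequence[SNPRecord],
    chin: ChIN,
    genes: Mapping[str, GeneRecord],
    flank: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, SNPTargets]:
    """Map GWAS SNPs to ChIN genes directly and through interactions.

    Direct hit: the SNP falls in the extended (+/- flank) gene body of a
    lincRNA or protein-coding gene present in the ChIN.  Inferred
    target: for a SNP inside a lincRNA genic region, or inside a DRE
    node that contacts a lincRNA promoter node, every gene whose
    promoter node is adjacent to the hit node in the ChIN.
    """
    chin_genes = [g for g in chin.gene_ids() if g in genes]
    genic_trees: dict[str, IntervalTree] = {}
    for gene_id in chin_genes:
        gene = genes[gene_id]
        if gene.biotype not in ("lincRNA", "protein_coding"):
            continue
        region = genic_region(gene, flank, chrom_sizes)
        genic_trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, gene_id
        )

    lincrna_nodes: set[int] = set()
    for gene_id in chin_genes:
        if genes[gene_id].biotype == "lincRNA":
            lincrna_nodes.update(chin.nodes_of_gene(gene_id))
    dre_trees: dict[str, IntervalTree] = {}
    for dre_id in chin.dre_nodes():
        if not any(nb in lincrna_nodes for nb in chin.neighbors(dre_id)):
            continue  # only DREs that contact a lincRNA promoter
        region = chin.node_region(dre_id)
        dre_trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, dre_id
        )

    known_chroms = set(genic_trees) | set(dre_trees) | {
        chin.node_region(i).chrom for i in chin.nodes
    }
    out: dict[str, SNPTargets] = {}
    for snp in snps:
        pos = snp.position
        if pos.chrom not in known_chroms:
            warnings.warn(f"SNP {snp.rsid} on unknown chromosome {pos.chrom}; skipped",
                          stacklevel=2)
            continue
        gtree = genic_trees.get(pos.chrom)
        direct = sorted(h.data for h in gtree.at(pos.start)) if gtree is not None else []
        inferred: set[str] = set()
        via: list[str] = []
        # through a lincRNA genic hit: partners of its promoter node(s)
        for gene_id in direct:
            if genes[gene_id].biotype != "lincRNA":
                continue
            via.append(f"lincRNA:{gene_id}")
            for node in chin.nodes_of_gene(gene_id):
                for nb in chin.neighbors(node):
                    inferred.update(g for g in chin.genes_on_node(nb) if g in genes)
        # through a DRE contacting lincRNA promoters
        dtree = dre_trees.get(pos.chrom)
        for hit in (dtree.at(pos.start) if dtree is not None else ()):
            via.append(f"dre:{hit.data}")
            for nb in chin.neighbors(hit.data):
                inferred.update(g for g in chin.genes_on_node(nb) if g in genes)
        inferred -= set(direct)
        out[snp.rsid] = SNPTargets(
            snp.rsid, snp.trait, direct, sorted(inferred), sorted(via)
        )
    return out
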