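"""RNA-level target prediction for lincRNAs.

Combines k-hop ChIN neighborhoods (spatially proximal genes) with
CHART/ChIRP binding peaks (genes bound at the RNA level) and expression
correlation into target calls, quantifies binding-by-proximity
enrichment with the permutation colocalization test, and contrasts
CHART coverage between the bound+interacting / bound-only /
interacting-only gene groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .annotation import genic_region
from .intervals import CoverageTrack, GenomicInterval
from .io import ExpressionMatrix, GeneRecord
from .network import ChIN, k_hop_neighborhood
from .stats import PermutationResult, expression_correlation, permutation_colocalization

logger = logging.getLogger(__name__)

GROUP_NAMES = ("bound_and_interacting", "bound_only", "interacting_only")


@dataclass
class TargetCall:
    lincrna_id: str
    gene_id: str
    evidence: frozenset[str]  # subset of {"interacting", "bound", "correlated"}
    k: int
    chart_mean_coverage: float

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a target call needs at least one line of evidence")


def interacting_genes(
    lincrna_id: str, chin: ChIN, k: int, genes: Mapping[str, GeneRecord]
) -> set[str]:
    """Genes on nodes within k hops of the lincRNA's promoter node(s)."""
    seeds = chin.nodes_of_gene(lincrna_id)
    if not seeds:
        warnings.warn(f"lincRNA {lincrna_id} has no promoter node in the ChIN",
                      stacklevel=2)
        return set()
    nodes = k_hop_neighborhood(chin, seeds, k)
    out: set[str] = set()
    for n in nodes:
        out.update(g for g in chin.genes_on_node(n) if g in genes)
    out.discard(lincrna_id)
    return out


def bound_genes(
    peaks: Sequence[GenomicInterval],
    genes: Mapping[str, GeneRecord],
    flank: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> set[str]:
    """Genes whose genic region (+/- flank of the body) overlaps >= 1 peak."""
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    out: set[str] = set()
    for gene_id, gene in genes.items():
        region = genic_region(gene, flank, chrom_sizes)
        tree = trees.get(region.chrom)
        if tree is not None and tree.overlap(region.start, region.end):
            out.add(gene_id)
    return out


def call_targets(
    lincrna_id: str,
    chin: ChIN,
    genes: Mapping[str, GeneRecord],
    peaks: Sequence[GenomicInterval],
    chart_track: CoverageTrack | None = None,
    expression: ExpressionMatrix | None = None,
    k: int = 3,
    r_threshold: float = 0.6,
    flank: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TargetCall]:
    """Call candidate target genes of one lincRNA.

    Evidence lines: ``interacting`` (within k ChIN hops, DRE-mediated
    paths included), ``bound`` (a binding peak overlaps the genic
    region by >= 1 bp) and ``correlated`` (expression correlation above
    the threshold).  A gene is called when it is interacting or bound;
    ``correlated`` only annotates calls.
    """
    inter = interacting_genes(lincrna_id, chin, k, genes)
    bound = bound_genes(peaks, genes, flank, chrom_sizes)
    bound.discard(lincrna_id)
    calls = []
    for gene_id in sorted(inter | bound):
        evidence = set()
        if gene_id in inter:
            evidence.add("interacting")
        if gene_id in bound:
            evidence.add("bound")
        if expression is not None and lincrna_id in expression.values.index \
                and gene_id in expression.values.index:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = expression_correlation(expression, lincrna_id, gene_id)
            if r > r_threshold:
                evidence.add("correlated")
        coverage = 0.0
        if chart_track is not None:
            coverage = chart_track.mean(genic_region(genes[gene_id], flank, chrom_sizes))
        calls.append(
            TargetCall(lincrna_id, gene_id, frozenset(evidence), k, coverage)
        )
    return calls


def three_groups(calls: Sequence[TargetCall]) -> dict[str, list[str]]:
    """Partition called genes into the three proximity/binding groups."""
    groups: dict[str, list[str]] = {name: [] for name in GROUP_NAMES}
    for call in calls:
        inter = "interacting" in call.evidence
        bound = "bound" in call.evidence
        if inter and bound:
            groups["bound_and_interacting"].append(call.gene_id)
        elif bound:
            groups["bound_only"].append(call.gene_id)
        elif inter:
            groups["interacting_only"].append(call.gene_id)
    return {name: sorted(g) for name, g in groups.items()}


def binding_enrichment_in_neighborhood(
    lincrna_id: str,
    chin: ChIN,
    peaks: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    k: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Are the lincRNA's binding peaks enriched in its k-hop neighborhood?

    set_a = binding peaks, set_b = node regions within k hops of the
    lincRNA's promoter node(s); delegates to the permutation
    colocalization test.
    """
    seeds = chin.nodes_of_gene(lincrna_id)
    if not seeds:
        warnings.warn(f"lincRNA {lincrna_id} has no promoter node in the ChIN",
                      stacklevel=2)
        return PermutationResult(0.0, 0.0, 0.0, float("nan"), 1.0, n_perm, seed)
    nodes = k_hop_neighborhood(chin, seeds, k)
    neighborhood = [chin.node_region(n) for n in sorted(nodes)]
    return permutation_colocalization(
        list(peaks), neighborhood, chrom_sizes, n_perm=n_perm, seed=seed
    )


def coverage_contrast(
    groups: Mapping[str, Sequence[str]],
    chart_track: CoverageTrack,
    genes: Mapping[str, GeneRecord],
    flank: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[dict[str, list[float]], dict[tuple[str, str], tuple[float, float]]]:
    """Per-group genic CHART coverage plus pairwise rank-sum comparisons.

    Returns (group -> per-gene mean coverages, (group_a, group_b) ->
    (U statistic, p)).  Comparisons involving an empty group are
    skipped and noted in the log.
    """
    from .stats import compare_groups

    values: dict[str, list[float]] = {}
    for name in groups:
        values[name] = [
            chart_track.mean(genic_region(genes[g], flank, chrom_sizes))
            for g in groups[name]
        ]
    comparisons: dict[tuple[str, str], tuple[float, float]] = {}
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if not values[a] or not values[b]:
                logger.info("skipping comparison %s vs %s: empty group", a, b)
                continue
            comparisons[(a, b)] = compare_groups(values[a], values[b])
    return values, comparisons
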