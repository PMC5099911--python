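"""Seeded synthetic-data generators with a manifest of planted truth.

The generators emulate the shape of the real inputs — ChIA-PET
interaction clusters, GENCODE-style annotation, histone coverage
tracks, ChromHMM segmentations, expression matrices, binding peaks,
GWAS SNP tables — at desk scale, and record every planted attribute in
a manifest so each pipeline stage has a recoverable ground truth.

Genome layout: each gene occupies a fixed-width slot (default 10 kb).
The gene body sits at [slot+3000, slot+5000); promoter windows,
extended genic regions and the slot's DRE zone ([slot+8000, slot+9500))
never cross slot boundaries, so merged anchor nodes carry exactly one
gene and planted interaction categories are recovered exactly by the
deterministic classification cascade.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .intervals import CoverageTrack, GenomicInterval
from .io import (
    BIOTYPES,
    ExpressionMatrix,
    GeneRecord,
    InteractionCluster,
    SNPRecord,
)

logger = logging.getLogger(__name__)

SLOT = 10_000
BODY_OFFSET = 3_000
BODY_LENGTH = 2_000
DRE_ZONE_OFFSET = 8_000
DRE_ZONE_LENGTH = 1_500

SUBCELLULAR_FRACTIONS = (
    "cell", "chromatin", "nucleus", "nucleolus", "nucleoplasm", "cytosol",
)

DEFAULT_BIOTYPE_MIX = {
    "protein_coding": 0.60,
    "lincRNA": 0.25,
    "antisense": 0.10,
    "miRNA": 0.05,
}

#: Planted C1..C5 counts for the desk preset's 50 lincRNAs.  The real
#: census is dominated by C5 (untranscribed, no contacts); the desk mix
#: keeps that skew while leaving enough C1 lincRNAs for the downstream
#: correlation/GSEA/target stages to have material to work on.
DEFAULT_CATEGORY_TARGETS = {"C1": 15, "C2": 8, "C3": 7, "C4": 8, "C5": 12}

#: Fraction of lincRNA promoters planted enhancer-like (the H3K4me1-
#: dominant stratum); protein-coding promoters are nearly all
#: promoter-like.
LINC_ENHANCER_FRACTION = 0.4
PC_ENHANCER_FRACTION = 0.1


# ---------------------------------------------------------------------------
# Genome + annotation


def make_genome(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 200,
    biotype_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Generate a chrom.sizes map and a non-overlapping gene annotation.

    Genes are packed into fixed slots so bodies never overlap (lincRNAs
    are intergenic by construction).  Biotypes are shuffled over slots
    with the requested mix.
    """
    if biotype_mix is None:
        biotype_mix = DEFAULT_BIOTYPE_MIX
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    if n_genes == 0:
        return [], chrom_sizes
    slots_per_chrom = chrom_length // SLOT
    if n_genes > slots_per_chrom * n_chrom:
        raise ValueError(
            f"cannot pack {n_genes} genes into {n_chrom} x {chrom_length} bp; "
            f"increase chromosome length (need {SLOT} bp per gene)"
        )
    rng = np.random.default_rng(seed)

    biotypes: list[str] = []
    items = sorted(biotype_mix.items())
    for bt, frac in items:
        if bt not in BIOTYPES:
            raise ValueError(f"unknown biotype {bt!r} in mix")
        biotypes.extend([bt] * int(round(frac * n_genes)))
    while len(biotypes) < n_genes:
        biotypes.append("protein_coding")
    biotypes = list(rng.permutation(biotypes[:n_genes]))

    genes: list[GeneRecord] = []
    for i in range(n_genes):
        chrom = f"chr{i // slots_per_chrom + 1}"
        slot = (i % slots_per_chrom) * SLOT
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(
            chrom, slot + BODY_OFFSET, slot + BODY_OFFSET + BODY_LENGTH, strand
        )
        n_tss = int(rng.integers(1, 4))
        offsets = sorted({0, *(int(o) for o in rng.integers(0, 800, size=n_tss - 1))})
        if strand == "-":
            tss_list = tuple(sorted(body.end - 1 - o for o in offsets))
        else:
            tss_list = tuple(sorted(body.start + o for o in offsets))
        bt = biotypes[i]
        prefix = {"protein_coding": "PC", "lincRNA": "LINC", "antisense": "AS",
                  "miRNA": "MIR"}.get(bt, "G")
        gene_id = f"{prefix}{i:04d}"
        genes.append(GeneRecord(gene_id, gene_id, bt, body, tss_list))
    return genes, chrom_sizes


def _promoter_anchor(gene: GeneRecord) -> GenomicInterval:
    """A fixed anchor inside the gene's canonical promoter window."""
    tss = gene.canonical_tss
    return GenomicInterval(gene.chrom, tss - 400, tss + 400)


def _slot_of(gene: GeneRecord) -> int:
    return (gene.body.start // SLOT) * SLOT


def _dre_anchor(gene: GeneRecord, offset: int = 0, width: int = 300) -> GenomicInterval:
    """An anchor inside the gene's slot DRE zone, clear of all promoters."""
    start = _slot_of(gene) + DRE_ZONE_OFFSET + offset
    assert offset + width <= DRE_ZONE_LENGTH
    return GenomicInterval(gene.chrom, start, start + width)


# ---------------------------------------------------------------------------
# Interactions


def sample_powerlaw_degrees(
    n: int, exponent: float = 2.5, max_degree: int | None = None, seed: int = 0
) -> np.ndarray:
    """n i.i.d. draws from the discrete power law P(k) ~ k^-exponent, k >= 1."""
    rng = np.random.default_rng(seed)
    deg = rng.zipf(exponent, size=n)
    if max_degree is not None:
        deg = np.minimum(deg, max_degree)
    return deg


def make_powerlaw_graph(n: int, exponent: float = 2.5, seed: int = 0) -> nx.Graph:
    """A simple configuration-model graph with power-law degrees."""
    deg = sample_powerlaw_degrees(n, exponent, max_degree=int(np.sqrt(n) * 10), seed=seed)
    if deg.sum() % 2:
        deg[0] += 1
    g = nx.configuration_model(deg.tolist(), seed=int(seed))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def make_interactions(
    genes: Sequence[GeneRecord],
    category_targets: Mapping[str, int] | None = None,
    exponent: float = 2.5,
    n_scaffold_edges: int = 250,
    seed: int = 0,
) -> tuple[list[InteractionCluster], dict]:
    """Wire interaction clusters that force planted lincRNA categories.

    Each lincRNA's edges are chosen so the classification cascade must
    return its planted category: C1 contacts 1-3 protein-coding
    promoters, C2 contacts antisense/miRNA promoters only, C3 contacts
    a private DRE anchor in its own slot, C4/C5 get no anchors at all.
    Additional promoter-promoter scaffold edges among protein-coding
    genes follow a power-law degree target with the given exponent.
    """
    rng = np.random.default_rng(seed)
    lincs = sorted((g for g in genes if g.biotype == "lincRNA"), key=lambda g: g.gene_id)
    pcs = sorted((g for g in genes if g.biotype == "protein_coding"),
                 key=lambda g: g.gene_id)
    small_nc = sorted((g for g in genes if g.biotype in ("antisense", "miRNA")),
                      key=lambda g: g.gene_id)
    if category_targets is None:
        category_targets = _scale_category_targets(len(lincs))
    if sum(category_targets.values()) != len(lincs):
        raise ValueError(
            f"category targets sum to {sum(category_targets.values())}, "
            f"but there are {len(lincs)} lincRNAs"
        )
    if category_targets.get("C1", 0) > 0 and not pcs:
        raise ValueError("C1 lincRNAs require protein-coding genes")
    if category_targets.get("C2", 0) > 0 and not small_nc:
        raise ValueError("C2 lincRNAs require antisense/miRNA genes")

    order = list(rng.permutation(len(lincs)))
    categories: dict[str, str] = {}
    pos = 0
    for cat in ("C1", "C2", "C3", "C4", "C5"):
        for idx in order[pos:pos + category_targets.get(cat, 0)]:
            categories[lincs[idx].gene_id] = cat
        pos += category_targets.get(cat, 0)

    clusters: list[InteractionCluster] = []
    pairs: list[dict] = []
    genes_by_id = {g.gene_id: g for g in genes}
    used_pc_partners: set[str] = set()

    def add_edge(a: GenomicInterval, b: GenomicInterval) -> None:
        clusters.append(InteractionCluster(a, b, int(rng.integers(1, 11))))

    for lnc in lincs:
        cat = categories[lnc.gene_id]
        if cat == "C1":
            same_chrom = [p for p in pcs if p.chrom == lnc.chrom]
            pool = same_chrom or pcs
            fresh = [p for p in pool if p.gene_id not in used_pc_partners]
            n_partners = int(rng.integers(1, 4))
            # correlated-pair truth only covers partners not already tied to
            # another lincRNA, so each coding gene carries one planted r
            take = min(n_partners, len(fresh))
            chosen = []
            if take:
                idx = rng.choice(len(fresh), size=take, replace=False)
                chosen = [fresh[i] for i in sorted(idx)]
            extra_edges = []
            attempts = 0
            while len(chosen) + len(extra_edges) < n_partners and attempts < 20:
                cand = pool[int(rng.integers(0, len(pool)))]
                attempts += 1
                if cand not in chosen and cand not in extra_edges:
                    extra_edges.append(cand)
            for pc in chosen + extra_edges:
                add_edge(_promoter_anchor(lnc), _promoter_anchor(pc))
            for pc in chosen:
                used_pc_partners.add(pc.gene_id)
                dist = (
                    abs(lnc.canonical_tss - pc.canonical_tss)
                    if pc.chrom == lnc.chrom else None
                )
                pairs.append({
                    "lincrna": lnc.gene_id,
                    "partner": pc.gene_id,
                    "distance": dist,
                    "interaction": True,
                })
        elif cat == "C2":
            pool = [g for g in small_nc if g.chrom == lnc.chrom] or small_nc
            partner = pool[int(rng.integers(0, len(pool)))]
            add_edge(_promoter_anchor(lnc), _promoter_anchor(partner))
        elif cat == "C3":
            add_edge(_promoter_anchor(lnc), _dre_anchor(lnc, offset=0))
        # C4/C5: no anchors at all

    # protein-coding scaffold: preferential pairing toward power-law degrees
    target_deg = sample_powerlaw_degrees(
        len(pcs), exponent, max_degree=30, seed=int(rng.integers(2**31))
    )
    stubs: list[int] = []
    for i, d in enumerate(target_deg):
        stubs.extend([i] * int(d))
    stubs = list(rng.permutation(stubs))
    seen_pairs: set[tuple[int, int]] = set()
    n_added = 0
    for u, v in zip(stubs[::2], stubs[1::2]):
        if n_added >= n_scaffold_edges or u == v:
            continue
        key = (min(u, v), max(u, v))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        add_edge(_promoter_anchor(pcs[u]), _promoter_anchor(pcs[v]))
        n_added += 1
    # a few protein-coding gene <-> DRE contacts for anchor-type realism
    for pc in pcs[:: max(1, len(pcs) // 20)]:
        add_edge(_promoter_anchor(pc), _dre_anchor(pc, offset=500))

    clusters = [clusters[i] for i in rng.permutation(len(clusters))]
    truth = {
        "categories": categories,
        "pairs": pairs,
        "exponent": exponent,
        "used_partners": sorted(used_pc_partners),
    }
    return clusters, truth


def _scale_category_targets(n_lincs: int) -> dict[str, int]:
    total = sum(DEFAULT_CATEGORY_TARGETS.values())
    targets = {
        c: int(round(v * n_lincs / total)) for c, v in DEFAULT_CATEGORY_TARGETS.items()
    }
    targets["C5"] += n_lincs - sum(targets.values())
    return targets


# ---------------------------------------------------------------------------
# Coverage tracks + RNAPII peaks


def make_tracks(
    genes: Sequence[GeneRecord],
    labels: Mapping[str, str],
    rnapii_genes: Sequence[str],
    snr: float = 4.0,
    base_rate: float = 5.0,
    bin_size: int = 100,
    half_width: int = 2500,
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack, list[GenomicInterval]]:
    """Plant H3K4me1/H3K4me3 promoter signal and RNAPII peaks.

    An enhancer-like promoter draws per-bin me1 counts from
    Poisson(base_rate * snr) and me3 from Poisson(base_rate); a
    promoter-like promoter swaps the two.  RNAPII narrowPeak-style
    peaks are emitted at the promoters of ``rnapii_genes``.
    """
    if snr < 1:
        raise ValueError("snr must be >= 1")
    rng = np.random.default_rng(seed)
    me1_records, me3_records = [], []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.body.start)):
        label = labels.get(gene.gene_id)
        if label is None:
            continue
        if label not in ("enhancer_like", "promoter_like"):
            raise ValueError(f"bad promoter label {label!r} for {gene.gene_id}")
        tss = gene.canonical_tss
        start = tss - half_width
        me1_rate = base_rate * snr if label == "enhancer_like" else base_rate
        me3_rate = base_rate if label == "enhancer_like" else base_rate * snr
        n_bins = (2 * half_width) // bin_size
        me1 = rng.poisson(me1_rate, size=n_bins)
        me3 = rng.poisson(me3_rate, size=n_bins)
        for b in range(n_bins):
            s = start + b * bin_size
            if me1[b] > 0:
                me1_records.append((gene.chrom, s, s + bin_size, float(me1[b])))
            if me3[b] > 0:
                me3_records.append((gene.chrom, s, s + bin_size, float(me3[b])))
    peaks = []
    for gene_id in sorted(set(rnapii_genes)):
        gene = next(g for g in genes if g.gene_id == gene_id)
        tss = gene.canonical_tss
        peaks.append(GenomicInterval(gene.chrom, tss - 200, tss + 300))
    peaks.sort()
    return (
        CoverageTrack(me1_records, library_depth=1e6),
        CoverageTrack(me3_records, library_depth=1e6),
        peaks,
    )


# ---------------------------------------------------------------------------
# Expression


def make_expression(
    genes: Sequence[GeneRecord],
    pair_correlations: Sequence[tuple[str, str, float]],
    specific_genes: Mapping[str, str],
    zero_genes: Sequence[str] = (),
    n_cells: int = 55,
    n_samples: int = 108,
    base_log2_mean: float = 4.0,
    log2_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Log-normal RPKM matrix with planted pair correlations and
    cell-exclusive genes.

    Listed gene pairs share bivariate-normal per-sample noise in log2
    space with the stated correlation.  A gene in ``specific_genes``
    gets its target-cell maximum forced to >= 4x the maximum elsewhere
    (construction guarantee for the fold-change >= 2 rule).  Genes in
    ``zero_genes`` (the untranscribed stratum) are all-zero rows.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in sorted(genes, key=lambda g: g.gene_id)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for a, b, r in pair_correlations:
        if not (-1 < r < 1):
            raise ValueError(f"planted correlation must be in (-1, 1), got {r}")
        if a not in gene_index or b not in gene_index:
            raise ValueError(f"planted pair ({a}, {b}) not in annotation")

    cells = [f"CELL{i + 1:02d}" for i in range(n_cells)]
    sample_ids, cell_col, frac_col = [], [], []
    for s in range(n_samples):
        cell = cells[s % n_cells]
        frac = SUBCELLULAR_FRACTIONS[s % len(SUBCELLULAR_FRACTIONS)]
        sample_ids.append(f"S{s + 1:03d}_{cell}")
        cell_col.append(cell)
        frac_col.append(frac)

    mu = rng.normal(base_log2_mean, 1.0, size=len(gene_ids))
    noise = rng.normal(0.0, log2_sd, size=(len(gene_ids), n_samples))
    # one latent sample factor per source gene; partners are conditionally
    # independent given it, each with its own planted correlation
    by_source: dict[str, list[tuple[str, float]]] = {}
    seen_partners: set[str] = set()
    for a, b, r in pair_correlations:
        if b in seen_partners:
            raise ValueError(f"partner {b} appears in more than one planted pair")
        seen_partners.add(b)
        by_source.setdefault(a, []).append((b, r))
    for a in sorted(by_source):
        za = rng.normal(0.0, 1.0, size=n_samples)
        noise[gene_index[a]] = za * log2_sd
        for b, r in by_source[a]:
            zb = r * za + np.sqrt(1 - r * r) * rng.normal(0.0, 1.0, size=n_samples)
            noise[gene_index[b]] = zb * log2_sd
    values = np.power(2.0, mu[:, None] + noise)

    import pandas as pd

    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"cell_type": cell_col, "fraction": frac_col}, index=sample_ids
    )
    for gene_id, cell in sorted(specific_genes.items()):
        if gene_id in set(zero_genes):
            raise ValueError(f"{gene_id} cannot be both zero and cell-specific")
        target_samples = [s for s, c in zip(sample_ids, cell_col) if c == cell]
        other_samples = [s for s in sample_ids if s not in set(target_samples)]
        max_else = float(df.loc[gene_id, other_samples].max())
        df.loc[gene_id, target_samples] = 4.0 * max_else + 1.0
    for gene_id in zero_genes:
        df.loc[gene_id] = 0.0
    df = df.round(4)
    return ExpressionMatrix(df, meta)


# ---------------------------------------------------------------------------
# Auxiliary inputs: segmentation, SEs, CHART peaks, CTCF/cohesin, SNPs


RAW_STATE_NAMES = {
    "4_Strong_Enhancer": "strong_enhancer",
    "6_Weak_Enhancer": "weak_enhancer",
    "10_Txn_Elongation": "txn_transition_elongation",
    "11_Weak_Txn": "weak_transcribed",
    "8_Insulator": "insulator",
    "12_Repressed": "polycomb_repressed",
    "13_Heterochrom": "heterochromatin_repetitive",
    "1_Active_Promoter": "others",
}


def make_segmentation(
    chrom_sizes: Mapping[str, int], seed: int = 0
) -> tuple[list[tuple[GenomicInterval, str]], dict[str, str]]:
    """Tile each chromosome with raw-named ChromHMM-style segments."""
    rng = np.random.default_rng(seed)
    raw_names = sorted(RAW_STATE_NAMES)
    segments = []
    for chrom in sorted(chrom_sizes):
        pos = 0
        size = chrom_sizes[chrom]
        while pos < size:
            length = int(rng.integers(1000, 4000))
            end = min(pos + length, size)
            name = raw_names[int(rng.integers(0, len(raw_names)))]
            segments.append((GenomicInterval(chrom, pos, end), name))
            pos = end
    return segments, dict(RAW_STATE_NAMES)


def make_super_enhancers(
    dre_regions: Sequence[GenomicInterval], fraction: float = 0.3, seed: int = 0
) -> list[GenomicInterval]:
    """Super-enhancer intervals covering a sample of DRE regions (padded)."""
    rng = np.random.default_rng(seed)
    chosen = [r for r in sorted(dre_regions) if rng.random() < fraction]
    ses = [GenomicInterval(r.chrom, max(0, r.start - 200), r.end + 200) for r in chosen]
    from .intervals import merge_intervals

    return merge_intervals(ses)


def make_chart_peaks(
    neighborhood: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    enrichment_factor: float = 10.0,
    base_rate: float = 0.1,
    n_background: int = 20,
    peak_width: int = 200,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Binding peaks enriched inside the k-hop neighborhood regions.

    Each neighborhood region receives a peak with probability
    min(1, base_rate * enrichment_factor); background peaks fall
    uniformly over the genome.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    p_in = min(1.0, base_rate * enrichment_factor)
    peaks = []
    for region in sorted(neighborhood):
        if rng.random() >= p_in:
            continue
        width = min(peak_width, region.length)
        start = region.start + int(rng.integers(0, region.length - width + 1))
        peaks.append(GenomicInterval(region.chrom, start, start + width))
    chroms = sorted(chrom_sizes)
    for _ in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - peak_width))
        peaks.append(GenomicInterval(chrom, start, start + peak_width))
    return sorted(peaks)


def make_ctcf_inputs(
    genes: Sequence[GeneRecord], seed: int = 0
) -> tuple[list[InteractionCluster], list[GenomicInterval]]:
    """A small CTCF-mediated cluster set plus cohesin peaks on half its anchors."""
    rng = np.random.default_rng(seed)
    slots = sorted({(g.chrom, _slot_of(g)) for g in genes})
    clusters = []
    cohesin = []
    for i in range(0, len(slots) - 1, 4):
        (chrom_a, slot_a), (chrom_b, slot_b) = slots[i], slots[i + 1]
        if chrom_a != chrom_b:
            continue
        a = GenomicInterval(chrom_a, slot_a + DRE_ZONE_OFFSET + 1000,
                            slot_a + DRE_ZONE_OFFSET + 1300)
        b = GenomicInterval(chrom_b, slot_b + DRE_ZONE_OFFSET + 1000,
                            slot_b + DRE_ZONE_OFFSET + 1300)
        clusters.append(InteractionCluster(a, b, int(rng.integers(1, 6))))
        if rng.random() < 0.5:
            cohesin.append(GenomicInterval(a.chrom, a.start + 50, a.end - 50))
    return clusters, cohesin


def make_snps(
    genes: Sequence[GeneRecord],
    target_lincs: Sequence[str],
    chrom_sizes: Mapping[str, int],
    n_background: int = 10,
    seed: int = 0,
) -> list[SNPRecord]:
    """SNPs planted inside chosen lincRNA bodies, plus uniform background."""
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    snps = []
    for i, lnc_id in enumerate(sorted(target_lincs)):
        gene = by_id[lnc_id]
        pos = gene.body.start + 100
        snps.append(SNPRecord(
            f"rs{900000 + i}",
            GenomicInterval(gene.chrom, pos, pos + 1),
            "synthetic_trait",
        ))
    chroms = sorted(chrom_sizes)
    for j in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, chrom_sizes[chrom] - 1))
        snps.append(SNPRecord(
            f"rs{100000 + j}", GenomicInterval(chrom, pos, pos + 1), "background"
        ))
    return snps


def make_gene_sets(
    genes: Sequence[GeneRecord],
    n_sets: int = 12,
    extra_sets: Mapping[str, set[str]] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Gene sets over protein-coding genes (random block sets), plus any
    planted sets (e.g. the focus lincRNA's co-expression module)."""
    pcs = sorted(g.gene_id for g in genes if g.biotype == "protein_coding")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(pcs))
    sets: dict[str, set[str]] = {}
    block = max(5, len(pcs) // n_sets)
    for i in range(n_sets):
        members = shuffled[i * block:(i + 1) * block]
        if len(members) < 5:
            members = shuffled[:5]
        sets[f"GO_SET_{i + 1:02d}"] = set(members)
    if extra_sets:
        sets.update({k: set(v) for k, v in extra_sets.items()})
    return sets


# ---------------------------------------------------------------------------
# Orchestration + manifest


@dataclass
class SyntheticManifest:
    seed: int
    chrom_sizes: dict[str, int]
    biotypes: dict[str, str]
    categories: dict[str, str]              # lincRNA -> planted C1..C5
    promoter_labels: dict[str, str]         # gene -> planted enh/prom-like
    specific_genes: dict[str, str]          # gene -> exclusive cell type
    pairs: list[dict]                       # planted correlated pairs
    pair_correlation: float
    exponent: float
    focus_lincrna: str | None
    focus_module: list[str]
    enrichment_factor: float
    hop_k: int
    se_linked_lincrnas: list[str]
    snp_truth: dict[str, dict]              # rsid -> {lincrna, expected_targets}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedInputs:
    """In-memory handles plus the file paths written by :func:`simulate`."""

    manifest: SyntheticManifest
    genes: list[GeneRecord]
    chrom_sizes: dict[str, int]
    clusters: list[InteractionCluster]
    paths: dict[str, str]


def simulate(
    outdir: str | Path,
    seed: int = 0,
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 200,
    category_targets: Mapping[str, int] | None = None,
    exponent: float = 2.5,
    snr: float = 4.0,
    pair_r: float = 0.8,
    enrichment_factor: float = 10.0,
    hop_k: int = 3,
) -> SimulatedInputs:
    """Generate the full desk-scale input bundle and its truth manifest.

    Writes annotation.gtf, clusters.bedpe, chrom.sizes, me1/me3
    bedGraphs, rnapii_peaks.bed, segmentation.bed + state_mapping.tsv,
    super_enhancers.bed, chart_peaks.bed, ctcf_clusters.bedpe,
    cohesin_peaks.bed, expression.tsv + samples.tsv, snps.tsv,
    gene_sets.gmt, and manifest.json into ``outdir``.
    """
    from . import io as lio
    from .annotation import promoter_windows, se_linked_lincrnas
    from .network import build_chin, k_hop_neighborhood

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731 - sequential child seeds

    genes, chrom_sizes = make_genome(n_chrom, chrom_length, n_genes, seed=sub())
    clusters, inter_truth = make_interactions(
        genes, category_targets, exponent, seed=sub()
    )
    categories = inter_truth["categories"]
    genes_by_id = {g.gene_id: g for g in genes}

    # promoter labels: lincRNAs split enh/prom-like, coding mostly prom-like
    label_rng = np.random.default_rng(sub())
    promoter_labels: dict[str, str] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.biotype == "lincRNA":
            frac = LINC_ENHANCER_FRACTION
        elif g.biotype == "protein_coding":
            frac = PC_ENHANCER_FRACTION
        else:
            continue
        promoter_labels[g.gene_id] = (
            "enhancer_like" if label_rng.random() < frac else "promoter_like"
        )

    rnapii_genes = [
        g.gene_id for g in genes
        if g.biotype == "protein_coding"
        or categories.get(g.gene_id) in ("C1", "C2", "C3", "C4")
    ]
    me1, me3, rnapii_peaks = make_tracks(
        genes, promoter_labels, rnapii_genes, snr=snr, seed=sub()
    )

    zero_genes = sorted(g for g, c in categories.items() if c == "C5")
    c1_lincs = sorted(g for g, c in categories.items() if c == "C1")
    focus = c1_lincs[0] if c1_lincs else None

    # co-expression module for the focus lincRNA: its interaction partners
    # plus additional coding genes, all sharing one latent expression
    # factor with it — the guilt-by-association stage should find the
    # matching gene set enriched
    module_genes: list[str] = []
    if focus is not None:
        partners = [
            p["partner"] for p in inter_truth["pairs"] if p["lincrna"] == focus
        ]
        free_pcs = sorted(
            g.gene_id for g in genes
            if g.biotype == "protein_coding"
            and g.gene_id not in set(inter_truth["used_partners"])
        )
        mod_rng = np.random.default_rng(sub())
        n_extra = max(0, 8 - len(partners))
        extra = [str(x) for x in mod_rng.choice(free_pcs, size=n_extra,
                                                replace=False)]
        module_genes = sorted(partners + extra)
        inter_truth["pairs"] += [
            {"lincrna": focus, "partner": g, "distance": None,
             "interaction": False}
            for g in sorted(extra)
        ]

    pair_correlations = [
        (p["lincrna"], p["partner"], pair_r if p["interaction"] else 0.75)
        for p in inter_truth["pairs"]
    ]
    # cell-exclusive lincRNAs are planted outside the correlated C1 pairs:
    # the specificity forcing would otherwise overwrite the planted
    # correlation structure of those rows
    specific_pool = sorted(g for g, c in categories.items() if c in ("C2", "C3"))
    spec_rng = np.random.default_rng(sub())
    specific_genes = {
        g: f"CELL{int(spec_rng.integers(1, 56)):02d}" for g in specific_pool[:5]
    }
    expression = make_expression(
        genes, pair_correlations, specific_genes, zero_genes, seed=sub()
    )

    promoters = {
        g.gene_id: promoter_windows(g, chrom_sizes=chrom_sizes) for g in genes
    }
    chin = build_chin(clusters, promoters)

    segmentation, state_mapping = make_segmentation(chrom_sizes, seed=sub())
    dre_regions = [chin.node_region(i) for i in chin.dre_nodes()]
    super_enhancers = make_super_enhancers(dre_regions, seed=sub())
    se_linked = sorted(se_linked_lincrnas(chin, genes_by_id, super_enhancers))

    chart_peaks: list[GenomicInterval] = []
    if focus is not None:
        nodes = k_hop_neighborhood(chin, chin.nodes_of_gene(focus), hop_k)
        neighborhood = [chin.node_region(n) for n in sorted(nodes)]
        chart_peaks = make_chart_peaks(
            neighborhood, chrom_sizes, enrichment_factor, seed=sub()
        )
    ctcf_clusters, cohesin_peaks = make_ctcf_inputs(genes, seed=sub())

    snp_lincs = c1_lincs[:3]
    snps = make_snps(genes, snp_lincs, chrom_sizes, seed=sub())
    snp_truth = {}
    for i, lnc_id in enumerate(sorted(snp_lincs)):
        partners = sorted(
            p["partner"] for p in inter_truth["pairs"]
            if p["lincrna"] == lnc_id and p["interaction"]
        )
        snp_truth[f"rs{900000 + i}"] = {
            "lincrna": lnc_id, "expected_targets": partners,
        }
    extra_sets = {"GO_FOCUS_MODULE": set(module_genes)} if module_genes else None
    gene_sets = make_gene_sets(genes, extra_sets=extra_sets, seed=sub())

    paths = {
        "annotation": str(outdir / "annotation.gtf"),
        "clusters": str(outdir / "clusters.bedpe"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "me1": str(outdir / "h3k4me1.bedgraph"),
        "me3": str(outdir / "h3k4me3.bedgraph"),
        "rnapii_peaks": str(outdir / "rnapii_peaks.bed"),
        "segmentation": str(outdir / "segmentation.bed"),
        "state_mapping": str(outdir / "state_mapping.tsv"),
        "super_enhancers": str(outdir / "super_enhancers.bed"),
        "chart_peaks": str(outdir / "chart_peaks.bed"),
        "ctcf_clusters": str(outdir / "ctcf_clusters.bedpe"),
        "cohesin_peaks": str(outdir / "cohesin_peaks.bed"),
        "expression": str(outdir / "expression.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "snps": str(outdir / "snps.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "manifest": str(outdir / "manifest.json"),
    }
    lio.write_gtf(genes, paths["annotation"])
    lio.write_bedpe(clusters, paths["clusters"])
    lio.write_chrom_sizes(chrom_sizes, paths["chrom_sizes"])
    lio.write_bedgraph(me1, paths["me1"])
    lio.write_bedgraph(me3, paths["me3"])
    lio.write_bed(rnapii_peaks, paths["rnapii_peaks"])
    lio.write_bed([iv for iv, _ in segmentation], paths["segmentation"],
                  names=[lab for _, lab in segmentation])
    with open(paths["state_mapping"], "w") as fh:
        for raw in sorted(state_mapping):
            fh.write(f"{raw}\t{state_mapping[raw]}\n")
    lio.write_bed(super_enhancers, paths["super_enhancers"])
    lio.write_bed(chart_peaks, paths["chart_peaks"])
    lio.write_bedpe(ctcf_clusters, paths["ctcf_clusters"])
    lio.write_bed(cohesin_peaks, paths["cohesin_peaks"])
    lio.write_expression(expression, paths["expression"], paths["samples"])
    lio.write_snps(snps, paths["snps"])
    lio.write_gmt(gene_sets, paths["gene_sets"])

    manifest = SyntheticManifest(
        seed=seed,
        chrom_sizes=dict(chrom_sizes),
        biotypes={g.gene_id: g.biotype for g in genes},
        categories=categories,
        promoter_labels=promoter_labels,
        specific_genes=specific_genes,
        pairs=inter_truth["pairs"],
        pair_correlation=pair_r,
        exponent=exponent,
        focus_lincrna=focus,
        focus_module=module_genes,
        enrichment_factor=enrichment_factor,
        hop_k=hop_k,
        se_linked_lincrnas=se_linked,
        snp_truth=snp_truth,
    )
    manifest.to_json(paths["manifest"])
    return SimulatedInputs(manifest, genes, chrom_sizes, clusters, paths)
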