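"""Pipeline orchestration: the stages behind the CLI and the analysis
scripts.

Each stage is a function taking loaded inputs and returning in-memory
results plus writing deterministic TSV/JSON/GraphML artifacts.  Stages
never mutate each other's outputs; ``run_pipeline`` executes them in
dependency order (io -> network -> annotation -> classification ->
stats / rna_targets) and stamps the run log with the config hash and
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classification as cls
from . import io as lio
from . import network as net
from . import rna_targets as rt
from . import stats as st
from .config import PipelineConfig
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class LoadedInputs:
    genes: dict[str, lio.GeneRecord]
    clusters: list[lio.InteractionCluster]
    chrom_sizes: dict[str, int]
    me1: object
    me3: object
    rnapii_peaks: list[GenomicInterval]
    segmentation: list
    state_mapping: dict[str, str]
    super_enhancers: list[GenomicInterval]
    chart_peaks: list[GenomicInterval]
    ctcf_clusters: list[lio.InteractionCluster]
    cohesin_peaks: list[GenomicInterval]
    expression: lio.ExpressionMatrix
    snps: list[lio.SNPRecord]
    gene_sets: dict[str, set[str]]


def load_inputs(config: PipelineConfig) -> LoadedInputs:
    genes = {g.gene_id: g for g in lio.read_gtf(config.annotation)}
    chrom_sizes = lio.read_chrom_sizes(config.chrom_sizes)
    lio.check_chrom_dialect(
        (g.chrom for g in genes.values()), chrom_sizes.keys()
    )
    return LoadedInputs(
        genes=genes,
        clusters=lio.read_bedpe(config.clusters),
        chrom_sizes=chrom_sizes,
        me1=lio.read_bedgraph(config.me1, library_depth=1e6),
        me3=lio.read_bedgraph(config.me3, library_depth=1e6),
        rnapii_peaks=lio.read_bed(config.rnapii_peaks),
        segmentation=lio.read_segmentation(config.segmentation),
        state_mapping=lio.read_state_mapping(config.state_mapping),
        super_enhancers=lio.read_bed(config.super_enhancers),
        chart_peaks=lio.read_bed(config.chart_peaks),
        ctcf_clusters=lio.read_bedpe(config.ctcf_clusters),
        cohesin_peaks=lio.read_bed(config.cohesin_peaks),
        expression=lio.read_expression(config.expression, config.samples),
        snps=lio.read_snps(config.snps),
        gene_sets=lio.read_gmt(config.gene_sets),
    )


# ---------------------------------------------------------------------------
# Stages


def stage_network(inputs: LoadedInputs, config: PipelineConfig, outdir: Path):
    """Build the ChIN, its descriptors and communities; write GraphML + TSV."""
    promoters = {
        gid: ann.promoter_windows(
            g, config.promoter_half_width, inputs.chrom_sizes
        )
        for gid, g in inputs.genes.items()
    }
    chin = net.build_chin(inputs.clusters, promoters, config.merge_max_gap)
    descriptors = net.compute_descriptors(chin)
    communities = net.detect_communities(
        chin, seed=config.seed, min_size=config.community_min_size
    )

    net.write_graphml(chin, outdir / "network.graphml")
    desc = {
        "n_nodes": descriptors.n_nodes,
        "n_edges": descriptors.n_edges,
        "transitivity": descriptors.transitivity,
        "graph_density": descriptors.graph_density,
        "component_sizes": descriptors.component_sizes[:50],
        "degree_distribution": {
            str(k): v for k, v in descriptors.degree_distribution.items()
        },
        "kcore_distribution": {
            str(k): v for k, v in descriptors.kcore_distribution.items()
        },
        "power_law": (
            {
                "alpha": descriptors.power_law.alpha,
                "xmin": descriptors.power_law.xmin,
                "ks_distance": descriptors.power_law.ks_distance,
                "n_tail": descriptors.power_law.n_tail,
            }
            if descriptors.power_law
            else None
        ),
        "n_communities": communities.n_communities,
    }
    with open(outdir / "descriptors.json", "w") as fh:
        json.dump(desc, fh, indent=1, sort_keys=True)
    rows = [
        {
            "node_id": node_id,
            "region": str(chin.node_region(node_id)),
            "role": chin.nodes[node_id].role,
            "genes": ",".join(chin.genes_on_node(node_id)),
            "degree": chin.graph.degree(node_id),
            "community": communities.labels.get(node_id, -1),
        }
        for node_id in sorted(chin.nodes)
    ]
    pd.DataFrame(rows).to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    return chin, descriptors, communities


def stage_annotation(inputs, config, chin, outdir: Path):
    """Label DRE states, join super-enhancers, map SNPs to targets."""
    dres = {i: chin.node_region(i) for i in chin.dre_nodes()}
    dre_states = ann.label_dre_states(dres, inputs.segmentation, inputs.state_mapping)
    pd.DataFrame(
        [
            {"node_id": i, "region": str(dres[i]), "state": dre_states[i]}
            for i in sorted(dres)
        ]
    ).to_csv(outdir / "dre_states.tsv", sep="\t", index=False)

    se_map = ann.super_enhancer_overlap(dres, inputs.super_enhancers)
    se_linked = ann.se_linked_lincrnas(chin, inputs.genes, inputs.super_enhancers)
    pd.DataFrame(
        [
            {
                "se_index": i,
                "se_region": str(inputs.super_enhancers[i]),
                "dre_nodes": ",".join(map(str, dre_ids)),
            }
            for i, dre_ids in sorted(se_map.items())
        ]
    ).to_csv(outdir / "super_enhancer_overlap.tsv", sep="\t", index=False)

    snp_targets = ann.map_snps_to_targets(
        inputs.snps, chin, inputs.genes, config.genic_flank, inputs.chrom_sizes
    )
    pd.DataFrame(
        [
            {
                "rsid": t.rsid,
                "trait": t.trait,
                "direct_genes": ",".join(t.direct_genes),
                "inferred_targets": ",".join(t.inferred_targets),
                "via": ",".join(t.via),
            }
            for t in (snp_targets[r] for r in sorted(snp_targets))
        ]
    ).to_csv(outdir / "snp_targets.tsv", sep="\t", index=False)
    return dre_states, se_map, sorted(se_linked), snp_targets


def stage_classification(inputs, config, chin, outdir: Path):
    """Categories C1-C5, promoter profiles, cell specificity."""
    lincs = sorted(
        (g for g in inputs.genes.values() if g.biotype == "lincRNA"),
        key=lambda g: g.gene_id,
    )
    assignment = cls.classify_categories(
        lincs, chin, inputs.genes, inputs.rnapii_peaks, inputs.expression,
        config.promoter_half_width, inputs.chrom_sizes,
    )
    rows = []
    for g in lincs:
        ev = assignment.evidence[g.gene_id]
        rows.append({
            "gene_id": g.gene_id,
            "category": assignment.categories[g.gene_id],
            "n_coding_partners": ev.n_coding_partners,
            "n_noncoding_partners": ev.n_noncoding_partners,
            "n_dre_partners": ev.n_dre_partners,
            "n_rnapii_promoter_peaks": ev.n_rnapii_promoter_peaks,
            "max_rpkm": f"{ev.max_rpkm:.4f}",
        })
    pd.DataFrame(rows).to_csv(outdir / "categories.tsv", sep="\t", index=False)

    profiles = {}
    prof_rows = []
    for g in lincs + sorted(
        (g for g in inputs.genes.values() if g.biotype == "protein_coding"),
        key=lambda g: g.gene_id,
    ):
        p = cls.profile_promoter(
            g, inputs.me1, inputs.me3, config.epsilon,
            config.promoter_half_width, chrom_sizes=inputs.chrom_sizes,
        )
        profiles[g.gene_id] = p
        row = {"gene_id": g.gene_id, "biotype": inputs.genes[g.gene_id].biotype,
               "me1_2kb": f"{p.me1_2kb:.4f}", "me3_2kb": f"{p.me3_2kb:.4f}",
               "log2_ratio": f"{p.log2_ratio:.4f}", "label": p.label}
        for i, v in enumerate(p.me1_bins):
            row[f"me1_bin{i + 1:02d}"] = f"{v:.4f}"
        for i, v in enumerate(p.me3_bins):
            row[f"me3_bin{i + 1:02d}"] = f"{v:.4f}"
        prof_rows.append(row)
    pd.DataFrame(prof_rows).to_csv(
        outdir / "promoter_profiles.tsv", sep="\t", index=False
    )

    cell_types = sorted(inputs.expression.sample_meta["cell_type"].unique())
    spec_rows = []
    for g in lincs:
        if g.gene_id not in inputs.expression.values.index:
            continue
        best = None
        for cell in cell_types:
            r = cls.cell_specificity(
                inputs.expression, g.gene_id, cell, config.epsilon,
                config.specificity_fold_change,
            )
            if best is None or r.fold_change > best.fold_change:
                best = r
        spec_rows.append({
            "gene_id": g.gene_id,
            "best_cell": best.target_cell,
            "fold_change": f"{best.fold_change:.4f}",
            "is_specific": best.is_specific,
        })
    pd.DataFrame(spec_rows).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    return assignment, profiles


def stage_function_assignment(inputs, config, chin, assignment, outdir: Path):
    """Guilt-by-association: correlation ranking + preranked GSEA + matrix."""
    coding = sorted(
        g for g, rec in inputs.genes.items()
        if rec.biotype == "protein_coding" and g in inputs.expression.values.index
    )
    c1_lincs = sorted(
        g for g, c in assignment.categories.items()
        if c == "C1" and g in inputs.expression.values.index
    )
    gsea_results = {}
    rows = []
    for i, lnc in enumerate(c1_lincs):
        ranked = st.rank_genes_for_lincrna(inputs.expression, lnc, coding)
        results = st.gsea_preranked(
            ranked, inputs.gene_sets, weight_p=config.gsea_weight,
            n_perm=config.gsea_n_perm, seed=config.seed + i,
            fdr_threshold=config.gsea_fdr,
        )
        gsea_results[lnc] = results
        for r in results:
            rows.append({
                "lincrna": lnc, "term": r.term_id, "es": f"{r.es:.6f}",
                "nes": f"{r.nes:.6f}", "p_value": f"{r.p_value:.6f}",
                "fdr_q": f"{r.fdr_q:.6f}", "n_hits": r.n_hits,
            })
    pd.DataFrame(rows).to_csv(outdir / "gsea.tsv", sep="\t", index=False)

    matrix = None
    k = min(config.kmeans_k, len(c1_lincs), len(inputs.gene_sets))
    if k >= 2:
        try:
            matrix = st.build_association_matrix(
                gsea_results, k=k, seed=config.seed, fdr_threshold=config.gsea_fdr
            )
            matrix.values.to_csv(outdir / "association_matrix.tsv", sep="\t",
                                 float_format="%.4f")
        except ValueError as exc:
            logger.info("association matrix skipped: %s", exc)
    return gsea_results, matrix


def stage_communities_enrichment(inputs, config, chin, communities, outdir: Path):
    """Hypergeometric GO-style enrichment of large ChIN communities."""
    universe = {
        g for g in chin.gene_ids()
        if g in inputs.genes and inputs.genes[g].biotype == "protein_coding"
    }
    frames = []
    for label in communities.large_communities():
        members = communities.members(label)
        comm_genes = set()
        for node in members:
            comm_genes.update(
                g for g in chin.genes_on_node(node) if g in universe
            )
        if not comm_genes:
            continue
        df = st.enrich_community(comm_genes, universe, inputs.gene_sets)
        df.insert(0, "community", label)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=["community", "term", "n_overlap", "n_set", "n_community",
                     "n_universe", "odds_ratio", "p_value", "fdr_q"]
        )
    out.to_csv(outdir / "community_enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    return out


def stage_rna_targets(inputs, config, chin, assignment, outdir: Path):
    """k-hop target calls, binding enrichment, CHART coverage contrast."""
    c1_lincs = sorted(
        g for g, c in assignment.categories.items() if c == "C1"
    )
    focus = c1_lincs[0] if c1_lincs else None
    rows = []
    enrichment = {}
    if focus is not None:
        calls = rt.call_targets(
            focus, chin, inputs.genes, inputs.chart_peaks,
            chart_track=None, expression=inputs.expression,
            k=config.hop_k, r_threshold=config.correlation_threshold,
            flank=config.genic_flank, chrom_sizes=inputs.chrom_sizes,
        )
        for c in calls:
            rows.append({
                "lincrna": c.lincrna_id, "gene_id": c.gene_id,
                "interacting": "interacting" in c.evidence,
                "bound": "bound" in c.evidence,
                "correlated": "correlated" in c.evidence,
                "k": c.k,
            })
        res = rt.binding_enrichment_in_neighborhood(
            focus, chin, inputs.chart_peaks, inputs.chrom_sizes,
            k=config.hop_k, n_perm=config.n_perm, seed=config.seed,
        )
        enrichment[focus] = res
        with open(outdir / "binding_enrichment.json", "w") as fh:
            json.dump({focus: res.to_dict()}, fh, indent=1, sort_keys=True)
    pd.DataFrame(
        rows, columns=["lincrna", "gene_id", "interacting", "bound",
                       "correlated", "k"]
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)

    ctcf_chin = None
    if inputs.ctcf_clusters:
        ctcf_chin = net.build_chin(
            inputs.ctcf_clusters, {}, config.merge_max_gap
        )
        classes = cls.classify_binding_sites(
            inputs.chart_peaks, ctcf_chin, inputs.cohesin_peaks, chin
        )
        pd.DataFrame(
            [{"peak": str(c.peak), "class": c.site_class} for c in classes]
        ).to_csv(outdir / "binding_classes.tsv", sep="\t", index=False)
    return rows, enrichment


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns a summary dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)

    chin, descriptors, communities = stage_network(inputs, config, outdir)
    dre_states, se_map, se_linked, snp_targets = stage_annotation(
        inputs, config, chin, outdir
    )
    assignment, profiles = stage_classification(inputs, config, chin, outdir)
    gsea_results, matrix = stage_function_assignment(
        inputs, config, chin, assignment, outdir
    )
    stage_communities_enrichment(inputs, config, chin, communities, outdir)
    target_rows, enrichment = stage_rna_targets(
        inputs, config, chin, assignment, outdir
    )

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": len(inputs.genes),
        "n_clusters": len(inputs.clusters),
        "n_nodes": chin.n_nodes,
        "n_edges": chin.n_edges,
        "n_communities": communities.n_communities,
        "category_counts": assignment.counts(),
        "n_se_linked_lincrnas": len(se_linked),
        "n_snps_mapped": len(snp_targets),
        "n_target_calls": len(target_rows),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"config_hash={config.config_hash()}\nseed={config.seed}\n")
        for k in sorted(summary):
            fh.write(f"{k}={summary[k]}\n")
    return summary
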