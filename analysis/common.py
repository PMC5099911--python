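"""Shared plumbing for the numbered analysis scripts: locate the
synthetic input bundle under results/synthetic and build the loaded
inputs + ChIN every downstream step starts from."""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "synthetic"


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args()


def load_bundle(seed: int):
    """Load (or lazily regenerate) the synthetic bundle and build the ChIN."""
    from linc_chin.annotation import promoter_windows
    from linc_chin.config import PipelineConfig
    from linc_chin.network import build_chin
    from linc_chin.pipeline import load_inputs
    from linc_chin.synthetic import simulate

    warnings.simplefilter("ignore")
    if not (SIM_DIR / "manifest.json").exists():
        simulate(SIM_DIR, seed=seed)
    from linc_chin.synthetic import SyntheticManifest

    manifest = SyntheticManifest.from_json(SIM_DIR / "manifest.json")
    paths = {p.stem.replace(".", "_"): str(p) for p in SIM_DIR.iterdir()}
    config = PipelineConfig(
        annotation=str(SIM_DIR / "annotation.gtf"),
        clusters=str(SIM_DIR / "clusters.bedpe"),
        chrom_sizes=str(SIM_DIR / "chrom.sizes"),
        me1=str(SIM_DIR / "h3k4me1.bedgraph"),
        me3=str(SIM_DIR / "h3k4me3.bedgraph"),
        rnapii_peaks=str(SIM_DIR / "rnapii_peaks.bed"),
        segmentation=str(SIM_DIR / "segmentation.bed"),
        state_mapping=str(SIM_DIR / "state_mapping.tsv"),
        super_enhancers=str(SIM_DIR / "super_enhancers.bed"),
        chart_peaks=str(SIM_DIR / "chart_peaks.bed"),
        ctcf_clusters=str(SIM_DIR / "ctcf_clusters.bedpe"),
        cohesin_peaks=str(SIM_DIR / "cohesin_peaks.bed"),
        expression=str(SIM_DIR / "expression.tsv"),
        samples=str(SIM_DIR / "samples.tsv"),
        snps=str(SIM_DIR / "snps.tsv"),
        gene_sets=str(SIM_DIR / "gene_sets.gmt"),
        seed=seed,
        n_perm=200,
    )
    config.validate()
    inputs = load_inputs(config)
    promoters = {
        gid: promoter_windows(g, config.promoter_half_width, inputs.chrom_sizes)
        for gid, g in inputs.genes.items()
    }
    chin = build_chin(inputs.clusters, promoters, config.merge_max_gap)
    return manifest, config, inputs, chin


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
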