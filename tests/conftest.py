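"""Shared fixtures: one desk-scale synthetic bundle and one pipeline run,
generated once per session and reused across test modules."""

from __future__ import annotations

import warnings

import pytest

from linc_chin.annotation import promoter_windows
from linc_chin.config import PipelineConfig
from linc_chin.network import build_chin
from linc_chin.pipeline import run_pipeline
from linc_chin.synthetic import simulate

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("desk_sim")
    return simulate(outdir, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_genes(desk_sim):
    return {g.gene_id: g for g in desk_sim.genes}


@pytest.fixture(scope="session")
def desk_chin(desk_sim, desk_genes):
    promoters = {
        gid: promoter_windows(g, chrom_sizes=desk_sim.chrom_sizes)
        for gid, g in desk_genes.items()
    }
    return build_chin(desk_sim.clusters, promoters)


@pytest.fixture(scope="session")
def desk_config(desk_sim):
    return PipelineConfig.from_paths(
        desk_sim.paths, seed=DESK_SEED, n_perm=200, gsea_n_perm=200
    )


@pytest.fixture(scope="session")
def desk_run(desk_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("desk_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = run_pipeline(desk_config, outdir)
    return outdir, summary
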