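"""Guilt-by-association function assignment and community enrichment.

For each C1 lincRNA, ranks protein-coding genes by expression
correlation (Pearson on log2(RPKM+1) across the sample panel), runs
preranked GSEA against the gene-set library, builds the lincRNA x term
association matrix with seeded k-means clustering, and runs
hypergeometric enrichment on large ChIN communities. Writes
results/function/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_bundle, outdir, parse_args  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    manifest, config, inputs, chin = load_bundle(args.seed)
    from linc_chin.network import detect_communities
    from linc_chin.pipeline import (
        stage_classification,
        stage_communities_enrichment,
        stage_function_assignment,
    )

    out = outdir("function")
    assignment, _ = stage_classification(inputs, config, chin, out)
    gsea_results, matrix = stage_function_assignment(
        inputs, config, chin, assignment, out
    )
    n_sig = sum(
        sum(r.fdr_q <= config.gsea_fdr for r in res)
        for res in gsea_results.values()
    )
    print(f"GSEA: {len(gsea_results)} C1 lincRNAs x {len(inputs.gene_sets)} "
          f"gene sets; {n_sig} significant at FDR <= {config.gsea_fdr}")
    focus = manifest.focus_lincrna
    if focus in gsea_results and gsea_results[focus]:
        top = min(gsea_results[focus], key=lambda r: (r.p_value, -abs(r.nes)))
        print(f"  top term for {focus}: {top.term_id} "
              f"(ES={top.es:.2f}, NES={top.nes:.2f}, q={top.fdr_q:.4g}; "
              f"planted module: {top.term_id == 'GO_FOCUS_MODULE'})")
    if matrix is not None:
        print(f"association matrix {matrix.values.shape} clustered with "
              f"k-means (k={matrix.k})")

    communities = detect_communities(
        chin, seed=config.seed, min_size=config.community_min_size
    )
    enr = stage_communities_enrichment(inputs, config, chin, communities, out)
    print(f"community enrichment rows: {len(enr)} over "
          f"{len(communities.large_communities())} communities with >= "
          f"{config.community_min_size} nodes")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
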