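"""Annotate distal regulatory elements (DREs) and super-enhancers.

Maps each DRE node to its highest-priority ChromHMM chromatin state,
joins super-enhancers to the DREs they overlap, flags lincRNAs whose
promoters contact SE-overlapping DREs, and tests DRE/SE colocalization
with the permutation test. Writes results/annotation/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_bundle, outdir, parse_args  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    manifest, config, inputs, chin = load_bundle(args.seed)
    from collections import Counter

    from linc_chin.pipeline import stage_annotation
    from linc_chin.stats import permutation_colocalization

    out = outdir("annotation")
    dre_states, se_map, se_linked, _ = stage_annotation(inputs, config, chin, out)
    print("DRE chromatin states:", dict(sorted(Counter(dre_states.values()).items())))
    n_multi = sum(1 for d in se_map.values() if len(d) >= 2)
    print(f"super-enhancers overlapping >= 1 DRE: {len(se_map)} "
          f"({n_multi} overlap two or more)")
    print(f"SE-linked lincRNAs: {se_linked}")

    dres = [chin.node_region(i) for i in chin.dre_nodes()]
    res = permutation_colocalization(
        inputs.super_enhancers, dres, inputs.chrom_sizes,
        n_perm=config.n_perm, seed=config.seed,
    )
    print(f"SE/DRE colocalization: observed {res.observed:.0f}, "
          f"z = {res.z_score:.2f}, p = {res.p_value:.4g}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
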