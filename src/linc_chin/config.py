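"""Pipeline configuration: input paths plus the tunable thresholds.

Every default threshold is either a standard value of the analysis
(promoter half-width 2.5 kb, hop depth 3, correlation threshold 0.6,
fold-change 2, GSEA FDR 0.01, community size floor 20) or a documented
package decision (merge gap 0, epsilon pseudocount 0.01).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input paths
    annotation: str = ""
    clusters: str = ""
    chrom_sizes: str = ""
    me1: str = ""
    me3: str = ""
    rnapii_peaks: str = ""
    segmentation: str = ""
    state_mapping: str = ""
    super_enhancers: str = ""
    chart_peaks: str = ""
    ctcf_clusters: str = ""
    cohesin_peaks: str = ""
    expression: str = ""
    samples: str = ""
    snps: str = ""
    gene_sets: str = ""
    # parameters
    promoter_half_width: int = 2500
    genic_flank: int = 2500
    merge_max_gap: int = 0
    hop_k: int = 3
    epsilon: float = 0.01
    correlation_threshold: float = 0.6
    specificity_fold_change: float = 2.0
    gsea_fdr: float = 0.01
    gsea_weight: float = 1.0
    # separate permutation depth for GSEA: the smallest attainable
    # empirical p must sit well below the FDR target after BH correction
    gsea_n_perm: int = 2000
    community_min_size: int = 20
    kmeans_k: int = 10
    n_perm: int = 1000
    seed: int = 0

    REQUIRED_INPUTS = (
        "annotation", "clusters", "chrom_sizes", "me1", "me3", "rnapii_peaks",
        "segmentation", "state_mapping", "super_enhancers", "chart_peaks",
        "ctcf_clusters", "cohesin_peaks", "expression", "samples", "snps",
        "gene_sets",
    )

    def validate(self) -> None:
        """Raise on invalid parameters or missing inputs (all listed at once)."""
        problems = []
        for name in ("promoter_half_width", "genic_flank", "epsilon",
                     "correlation_threshold", "specificity_fold_change",
                     "gsea_fdr", "community_min_size", "kmeans_k", "n_perm",
                     "gsea_n_perm"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.hop_k < 0:
            problems.append("hop_k must be >= 0")
        if self.merge_max_gap < 0:
            problems.append("merge_max_gap must be >= 0")
        missing = [
            name for name in self.REQUIRED_INPUTS
            if not getattr(self, name) or not Path(getattr(self, name)).exists()
        ]
        if missing:
            problems.append(f"missing input files: {missing}")
        if problems:
            raise ValueError("; ".join(problems))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_paths(cls, paths: dict[str, str], **overrides) -> "PipelineConfig":
        data = {k: v for k, v in paths.items() if k in cls.__dataclass_fields__}
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
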