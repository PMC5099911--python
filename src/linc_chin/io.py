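"""Readers and writers for the external formats the pipeline touches.

BEDPE (interaction clusters), GTF (GENCODE attribute dialect, via
gffutils), bedGraph coverage, BED/narrowPeak, chrom.sizes, expression
TSV with a side-car sample-metadata TSV, GWAS SNP TSV, GMT gene sets,
and the ChromHMM state-name mapping table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GenomicInterval

logger = logging.getLogger(__name__)

#: Gene biotype vocabulary; anything else collapses to "others".
BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "antisense",
    "miRNA",
    "sense_overlapping",
    "sense_intronic",
    "processed_transcript",
    "others",
)


class FormatError(ValueError):
    """Malformed record in an input file; message carries the line number."""


@dataclass(frozen=True)
class InteractionCluster:
    """One ChIA-PET interaction cluster: two anchors plus PET support."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int = 1

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError(f"pet_count must be >= 1, got {self.pet_count}")

    @property
    def self_contact(self) -> bool:
        """True when both anchors are the identical region after parsing."""
        return (
            self.anchor_a.chrom == self.anchor_b.chrom
            and self.anchor_a.start == self.anchor_b.start
            and self.anchor_a.end == self.anchor_b.end
        )

    @property
    def intra_chromosomal(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom


@dataclass(frozen=True)
class GeneRecord:
    """A gene: stable id, biotype, stranded body, and its annotated TSSs."""

    gene_id: str
    name: str
    biotype: str
    body: GenomicInterval
    tss_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id} has an empty TSS list")
        for tss in self.tss_list:
            if not (self.body.start <= tss <= self.body.end):
                raise ValueError(
                    f"TSS {tss} of {self.gene_id} outside body {self.body}"
                )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.gene_id}")

    @property
    def canonical_tss(self) -> int:
        """The 5'-most TSS on the gene's strand."""
        if self.body.strand == "-":
            return max(self.tss_list)
        return min(self.tss_list)

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass(frozen=True)
class SNPRecord:
    """A GWAS-catalog SNP as a length-1 interval (0-based internally)."""

    rsid: str
    position: GenomicInterval
    trait: str = ""

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError(f"SNP {self.rsid} interval must have length 1")


class ExpressionMatrix:
    """Genes x samples RPKM matrix with per-sample cell-type metadata."""

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame) -> None:
        if (values.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        missing = set(values.columns) - set(sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if sample_meta["cell_type"].isna().any():
            raise ValueError("every sample needs a cell-type label")
        self.values = values
        self.sample_meta = sample_meta.loc[list(values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_values(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id} not in expression matrix")
        return self.values.loc[gene_id]

    def samples_for_cell(self, cell_type: str) -> list[str]:
        mask = self.sample_meta["cell_type"] == cell_type
        return list(self.sample_meta.index[mask])


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path: str | Path) -> list[InteractionCluster]:
    """Read interaction clusters from a 6(+1)-column BEDPE file.

    A missing 7th column defaults the PET count to 1.  Self-contact rows
    (identical anchors) are retained; downstream code checks the
    ``self_contact`` flag.
    """
    clusters: list[InteractionCluster] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path} line {lineno}: expected >= 6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                pet = int(fields[6]) if len(fields) > 6 and fields[6] != "." else 1
                clusters.append(InteractionCluster(a, b, pet))
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return clusters


def write_bedpe(clusters: Iterable[InteractionCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.anchor_a.chrom}\t{c.anchor_a.start}\t{c.anchor_a.end}\t"
                f"{c.anchor_b.chrom}\t{c.anchor_b.start}\t{c.anchor_b.end}\t"
                f"{c.pet_count}\n"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[GeneRecord]:
    """Parse a GENCODE-dialect GTF into GeneRecords.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    TSSs are collected from all transcripts of a gene (strand-aware);
    a gene without transcript features falls back to a single TSS taken
    from the gene feature itself.  Unknown gene_type values map to
    "others" with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes["gene_id"][0]
        name = gene.attributes.get("gene_name", [gene_id])[0]
        biotype = gene.attributes.get("gene_type", ["others"])[0]
        if biotype not in BIOTYPES:
            warnings.warn(
                f"gene {gene_id}: unknown gene_type {biotype!r}, using 'others'",
                stacklevel=2,
            )
            biotype = "others"
        body = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        tss: set[int] = set()
        for tx in db.children(gene, featuretype="transcript"):
            tss.add(tx.end - 1 if gene.strand == "-" else tx.start - 1)
        if not tss:
            tss.add(body.end - 1 if gene.strand == "-" else body.start)
        records.append(GeneRecord(gene_id, name, biotype, body, tuple(sorted(tss))))
    return records


def write_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as a minimal GENCODE-style GTF (gene + transcripts)."""
    with open(path, "w") as fh:
        fh.write("##description: synthetic annotation\n##format: gtf\n")
        for g in sorted(genes, key=lambda g: (g.body.chrom, g.body.start, g.gene_id)):
            attrs = (
                f'gene_id "{g.gene_id}"; gene_type "{g.biotype}"; '
                f'gene_name "{g.name}";'
            )
            fh.write(
                f"{g.body.chrom}\tsynthetic\tgene\t{g.body.start + 1}\t{g.body.end}\t"
                f".\t{g.body.strand}\t.\t{attrs}\n"
            )
            for i, tss in enumerate(g.tss_list, 1):
                if g.body.strand == "-":
                    t_start, t_end = g.body.start + 1, tss + 1
                else:
                    t_start, t_end = tss + 1, g.body.end
                tattrs = attrs + f' transcript_id "{g.gene_id}.t{i}";'
                fh.write(
                    f"{g.body.chrom}\tsynthetic\ttranscript\t{t_start}\t{t_end}\t"
                    f".\t{g.body.strand}\t.\t{tattrs}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph / BED / narrowPeak


def read_bedgraph(path: str | Path, library_depth: float | None = None) -> CoverageTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path} line {lineno}: expected 4 columns")
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return CoverageTrack(records, library_depth=library_depth)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ / narrowPeak reader; only the coordinates are kept."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: expected >= 3 columns")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_segmentation(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """ChromHMM-style BED4: column 4 is the raw state label."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path} line {lineno}: expected 4 columns (BED4)")
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
    return out


# ---------------------------------------------------------------------------
# chrom.sizes, state mapping, SNPs, expression, GMT


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_state_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV: raw segmentation label -> fixed state vocabulary."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            raw, vocab = line.split("\t")[:2]
            mapping[raw] = vocab
    return mapping


def read_snps(path: str | Path) -> list[SNPRecord]:
    """SNP TSV (rsid, chrom, pos_1based, trait); positions converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos_1based"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SNP table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        pos0 = int(row.pos_1based) - 1
        trait = getattr(row, "trait", "")
        out.append(
            SNPRecord(row.rsid, GenomicInterval(row.chrom, pos0, pos0 + 1), str(trait))
        )
    return out


def write_snps(snps: Sequence[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos_1based\ttrait\n")
        for s in snps:
            fh.write(
                f"{s.rsid}\t{s.position.chrom}\t{s.position.start + 1}\t{s.trait}\n"
            )


def read_expression(values_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression(matrix: ExpressionMatrix, values_path: str | Path,
                     meta_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t", float_format="%.6g")
    matrix.sample_meta.to_csv(meta_path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def check_chrom_dialect(*name_sets: Iterable[str]) -> None:
    """Hard error when inputs mix 'chr1' and '1' style chromosome names."""
    prefixed, bare = set(), set()
    for names in name_sets:
        for n in names:
            (prefixed if str(n).startswith("chr") else bare).add(str(n))
    if prefixed and bare:
        raise ValueError(
            "mixed chromosome-name dialects across inputs: "
            f"{sorted(prefixed)[:3]} vs {sorted(bare)[:3]}"
        )
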