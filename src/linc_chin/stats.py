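"""Inferential machinery.

Permutation colocalization of genomic region sets (regioneR-style
length-preserving random relocation), expression correlation, preranked
GSEA for guilt-by-association function assignment, hypergeometric
community enrichment, and Wilcoxon rank-sum group comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Permutation colocalization


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _overlap_count(
    starts: np.ndarray,
    lengths: np.ndarray,
    chrom_idx: np.ndarray,
    b_by_chrom: dict[int, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Count regions (rows: permutations) overlapping any merged B region.

    ``starts`` has shape (n_perm, n_regions); B regions per chromosome
    are merged, sorted and disjoint, so region [s, e) overlaps some B
    interval iff the first B interval with end > s starts before e.
    """
    counts = np.zeros(starts.shape[0], dtype=np.int64)
    for ci, (b_starts, b_ends) in b_by_chrom.items():
        mask = chrom_idx == ci
        if not mask.any():
            continue
        s = starts[:, mask]
        e = s + lengths[mask]
        j = np.searchsorted(b_ends, s, side="right")
        hit = (j < len(b_starts)) & (np.take(b_starts, j, mode="clip") < e)
        counts += hit.sum(axis=1)
    return counts


def permutation_colocalization(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "per_chromosome",
) -> PermutationResult:
    """Permutation test for colocalization of two region sets.

    Statistic: the number of set_a regions overlapping at least one
    set_b region.  Each permutation relocates every set_a region
    uniformly at random, preserving its length, on its own chromosome
    (``mode="per_chromosome"``) or anywhere in the genome
    (``mode="genome"``).  The p-value is the enrichment-side empirical
    (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not set_a or not set_b:
        raise ValueError("both region sets must be non-empty")
    if mode not in ("per_chromosome", "genome"):
        raise ValueError(f"unknown mode {mode!r}")
    for iv in set_a:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"chromosome {iv.chrom} missing from chrom_sizes")
        if iv.length > size:
            raise ValueError(f"region {iv} longer than its chromosome ({size} bp)")

    chroms = sorted(chrom_sizes)
    chrom_to_i = {c: i for i, c in enumerate(chroms)}
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)

    b_by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merge_intervals(set_b):
        ci = chrom_to_i.get(iv.chrom)
        if ci is None:
            continue
        bs, be = b_by_chrom.setdefault(ci, ([], []))  # type: ignore[assignment]
        bs.append(iv.start)
        be.append(iv.end)
    b_by_chrom = {
        ci: (np.asarray(bs, dtype=np.int64), np.asarray(be, dtype=np.int64))
        for ci, (bs, be) in b_by_chrom.items()
    }

    a_starts = np.array([iv.start for iv in set_a], dtype=np.int64)[None, :]
    a_lengths = np.array([iv.length for iv in set_a], dtype=np.int64)
    a_chrom = np.array([chrom_to_i[iv.chrom] for iv in set_a], dtype=np.int64)
    observed = int(_overlap_count(a_starts, a_lengths, a_chrom, b_by_chrom)[0])

    rng = np.random.default_rng(seed)
    n_a = len(set_a)
    if mode == "per_chromosome":
        span = sizes[a_chrom] - a_lengths + 1
        starts = rng.integers(0, span[None, :], size=(n_perm, n_a))
        perm_chrom = a_chrom
        null = _overlap_count(starts, a_lengths, perm_chrom, b_by_chrom)
    else:  # genome-wide: chromosome drawn proportional to placeable positions
        null = np.zeros(n_perm, dtype=np.int64)
        for p in range(n_perm):
            span = sizes[None, :] - a_lengths[:, None] + 1  # (n_a, n_chrom)
            span = np.maximum(span, 0)
            probs = span / span.sum(axis=1, keepdims=True)
            cidx = np.array(
                [rng.choice(len(chroms), p=probs[i]) for i in range(n_a)],
                dtype=np.int64,
            )
            st = rng.integers(0, sizes[cidx] - a_lengths + 1)
            null[p] = _overlap_count(st[None, :], a_lengths, cidx, b_by_chrom)[0]

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
    else:
        warnings.warn("degenerate permutation null (sd = 0); z undefined", stacklevel=2)
        z = float("nan")
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(observed, null_mean, null_sd, z, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Expression correlation and ranking


def expression_correlation(
    expression: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    transform: str = "log2",
    method: str = "pearson",
) -> float:
    """Correlation between two genes' expression profiles.

    Default: Pearson on log2(RPKM + 1).  Returns NaN (with a warning)
    when either transformed vector has zero variance.
    """
    va = expression.gene_values(gene_a).to_numpy(dtype=float)
    vb = expression.gene_values(gene_b).to_numpy(dtype=float)
    if va.size < 3:
        raise ValueError("need >= 3 shared samples for a correlation")
    if transform == "log2":
        va = np.log2(va + 1.0)
        vb = np.log2(vb + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.std(va) == 0 or np.std(vb) == 0:
        warnings.warn(
            f"zero variance for {gene_a} or {gene_b}; correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    if method == "pearson":
        return float(np.corrcoef(va, vb)[0, 1])
    if method == "spearman":
        return float(sps.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown method {method!r}")


def rank_genes_for_lincrna(
    expression: ExpressionMatrix,
    lincrna: str,
    coding_genes: Sequence[str],
    transform: str = "log2",
    method: str = "pearson",
) -> list[tuple[str, float]]:
    """Coding genes ranked by descending correlation with the lincRNA.

    Ties break lexicographically by gene_id for determinism; undefined
    correlations rank last (score NaN -> -inf for ordering).
    """
    scores = []
    for g in coding_genes:
        if g == lincrna:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = expression_correlation(expression, lincrna, g, transform, method)
        scores.append((g, r))
    return sorted(
        scores,
        key=lambda t: (-(t[1] if np.isfinite(t[1]) else -np.inf), t[0]),
    )


# ---------------------------------------------------------------------------
# Preranked GSEA


@dataclass
class GseaResult:
    term_id: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    n_hits: int


def enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight_p: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score of a ranked list.

    Hit positions increment the running sum proportionally to
    |score|^weight_p (uniformly when weight_p = 0 or all hit weights are
    zero); misses decrement uniformly.  The ES is the maximum deviation
    from zero of the running sum.
    """
    n = scores.size
    n_hits = int(hit_mask.sum())
    n_miss = n - n_hits
    if n_hits == 0 or n_miss == 0:
        raise ValueError("gene set must hit a strict, non-empty subset of the list")
    weights = np.abs(scores) ** weight_p if weight_p != 0 else np.ones(n)
    hit_w = weights * hit_mask
    total_hit = hit_w.sum()
    if total_hit == 0:  # all hit scores exactly zero: fall back to uniform
        hit_w = hit_mask.astype(float)
        total_hit = hit_w.sum()
    steps = hit_w / total_hit - (~hit_mask.astype(bool)).astype(float) / n_miss
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked_list: Sequence[tuple[str, float]],
    gene_sets: Mapping[str, set[str]],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    fdr_threshold: float = 0.01,
) -> list[GseaResult]:
    """Preranked GSEA over a correlation-ranked gene list.

    Null: gene-label permutation (random hit sets of the same size).
    NES = ES / mean(|null ES|) among same-sign null ES values; p is the
    same-sign empirical tail; FDR by Benjamini-Hochberg across terms.
    """
    genes = np.array([g for g, _ in ranked_list])
    scores = np.array([s for _, s in ranked_list], dtype=float)
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    pvals: list[float] = []
    for term in sorted(gene_sets):
        members = gene_sets[term]
        hit_idx = sorted(gene_pos[g] for g in members if g in gene_pos)
        if len(hit_idx) == 0:
            warnings.warn(f"gene set {term} has no members in the list; skipped",
                          stacklevel=2)
            continue
        if len(hit_idx) < min_size:
            continue
        if len(hit_idx) == n:
            raise ValueError(f"gene set {term} equals the whole universe")
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[hit_idx] = True
        es = enrichment_score(scores, hit_mask, weight_p)

        m = len(hit_idx)
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=m, replace=False)] = True
            null_es[i] = enrichment_score(scores, perm_mask, weight_p)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size:
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else float("nan")
            n_extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
            p = (1 + n_extreme) / (1 + same_sign.size)
        else:
            nes = float("nan")
            p = 1.0 / (1 + n_perm)
        results.append(GseaResult(term, es, nes, p, 1.0, len(hit_idx)))
        pvals.append(p)

    if results:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for res, q in zip(results, qvals):
            res.fdr_q = float(q)
    return results


# ---------------------------------------------------------------------------
# Association matrix


@dataclass
class AssociationMatrix:
    values: pd.DataFrame  # lincRNAs (rows) x GO terms (columns)
    row_clusters: dict[str, int]
    col_clusters: dict[str, int]
    k: int


def build_association_matrix(
    gsea_results: Mapping[str, Sequence[GseaResult]],
    k: int = 10,
    seed: int = 0,
    fdr_threshold: float = 0.01,
    cap: float = 4.0,
) -> AssociationMatrix:
    """LincRNA x GO-term signed-significance matrix, k-means clustered.

    Entries are sign(NES) * min(-log10 fdr_q, cap) for terms significant
    at the FDR threshold, 0 otherwise.  Rows and columns are clustered
    separately with seeded k-means (10 restarts).
    """
    rows = sorted(gsea_results)
    terms = sorted({r.term_id for res in gsea_results.values() for r in res})
    if len(rows) < k or len(terms) < k:
        raise ValueError(
            f"need >= k rows and columns for k-means (k={k}, "
            f"rows={len(rows)}, cols={len(terms)})"
        )
    mat = pd.DataFrame(0.0, index=rows, columns=terms)
    for lnc, res in gsea_results.items():
        for r in res:
            if r.fdr_q <= fdr_threshold and np.isfinite(r.nes):
                mat.loc[lnc, r.term_id] = float(
                    np.sign(r.nes) * min(-np.log10(max(r.fdr_q, 1e-300)), cap)
                )
    row_km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(mat.values)
    col_km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(mat.values.T)
    return AssociationMatrix(
        mat,
        dict(zip(rows, (int(l) for l in row_km.labels_))),
        dict(zip(terms, (int(l) for l in col_km.labels_))),
        k,
    )


# ---------------------------------------------------------------------------
# Hypergeometric community enrichment


def enrich_community(
    community_genes: set[str],
    universe_genes: set[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Returns a DataFrame (term, n_overlap, n_set, n_community, n_universe,
    odds_ratio, p_value, fdr_q) sorted by p.
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    if not community_genes <= universe_genes:
        raise ValueError("community genes must be a subset of the universe")
    n_u = len(universe_genes)
    n_c = len(community_genes)
    rows = []
    for term in sorted(gene_sets):
        term_genes = gene_sets[term] & universe_genes
        n_t = len(term_genes)
        if n_t == 0:
            continue
        n_o = len(term_genes & community_genes)
        # P(X >= n_o) for X ~ Hypergeom(N=n_u, K=n_t, n=n_c)
        p = float(sps.hypergeom.sf(n_o - 1, n_u, n_t, n_c))
        a, b = n_o, n_t - n_o
        c, d = n_c - n_o, n_u - n_t - (n_c - n_o)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append((term, n_o, n_t, n_c, n_u, odds, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "term", "n_overlap", "n_set", "n_community", "n_universe",
            "odds_ratio", "p_value",
        ],
    )
    if len(df):
        _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["fdr_q"] = q
        df = df.sort_values(["p_value", "term"]).reset_index(drop=True)
    else:
        df["fdr_q"] = []
    return df


# ---------------------------------------------------------------------------
# Group comparison


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (normal approximation, tie-corrected)."""
    if len(values_a) < 1 or len(values_b) < 1:
        raise ValueError("both groups need at least one value")
    res = sps.mannwhitneyu(values_a, values_b, alternative="two-sided",
                           method="asymptotic")
    return float(res.statistic), float(res.pvalue)
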