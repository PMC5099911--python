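"""Permutation colocalization, correlation, GSEA, enrichment, rank-sum."""

import math

import numpy as np
import pandas as pd
import pytest

from linc_chin.intervals import GenomicInterval
from linc_chin.io import ExpressionMatrix
from linc_chin.stats import (
    build_association_matrix,
    compare_groups,
    enrich_community,
    enrichment_score,
    expression_correlation,
    gsea_preranked,
    GseaResult,
    permutation_colocalization,
    rank_genes_for_lincrna,
)


def brute_force_es(scores, hits, weight_p):
    """Independent running-sum oracle for the GSEA enrichment score."""
    w = [abs(s) ** weight_p if weight_p != 0 else 1.0 for s in scores]
    hit_total = sum(wi for wi, h in zip(w, hits) if h)
    if hit_total == 0:
        w = [1.0] * len(scores)
        hit_total = sum(1 for h in hits if h)
    n_miss = len(scores) - sum(hits)
    running, best = 0.0, 0.0
    for s, h, wi in zip(scores, hits, w):
        running += wi / hit_total if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def _regions(rng, n, chrom_len, length, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, chrom_len - length))
        out.append(GenomicInterval(c, s, s + length))
    return out


class TestPermutationColocalization:
    SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}

    def test_self_overlap_is_ceiling(self):
        rng = np.random.default_rng(4)
        regions = _regions(rng, 60, 1_000_000, 2000)
        res = permutation_colocalization(regions, regions, self.SIZES,
                                         n_perm=200, seed=0)
        assert res.observed == len(regions)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.z_score > 3

    def test_degenerate_null_flagged(self):
        # sparse self-overlap: the null never hits, sd = 0, z undefined
        rng = np.random.default_rng(4)
        regions = _regions(rng, 8, 1_000_000, 150)
        with pytest.warns(UserWarning, match="degenerate"):
            res = permutation_colocalization(regions, regions, self.SIZES,
                                             n_perm=200, seed=0)
        assert res.observed == len(regions)
        assert math.isnan(res.z_score)

    def test_z_is_centered(self):
        # observed equal to null mean -> z = 0 by construction
        from linc_chin.stats import PermutationResult

        r = PermutationResult(5.0, 5.0, 2.0, (5.0 - 5.0) / 2.0, 0.5, 100, 0)
        assert r.z_score == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        a = _regions(rng, 20, 1_000_000, 500)
        b = _regions(rng, 20, 1_000_000, 500)
        r1 = permutation_colocalization(a, b, self.SIZES, n_perm=100, seed=7)
        r2 = permutation_colocalization(a, b, self.SIZES, n_perm=100, seed=7)
        assert r1 == r2

    def test_region_longer_than_chromosome_rejected(self):
        big = [GenomicInterval("chr1", 0, 2_000_000)]
        with pytest.raises(ValueError, match="longer than"):
            permutation_colocalization(big, big, self.SIZES, n_perm=10, seed=0)

    def test_attainable_pvalues_are_lattice_points(self):
        rng = np.random.default_rng(6)
        n_perm = 50
        for rep in range(10):
            a = _regions(rng, 10, 1_000_000, 1000)
            b = _regions(rng, 10, 1_000_000, 1000)
            res = permutation_colocalization(a, b, self.SIZES, n_perm=n_perm,
                                             seed=rep)
            k = res.p_value * (n_perm + 1)
            assert k == pytest.approx(round(k))

    def test_genome_mode_runs(self):
        rng = np.random.default_rng(7)
        a = _regions(rng, 5, 1_000_000, 500)
        b = _regions(rng, 5, 1_000_000, 500)
        res = permutation_colocalization(a, b, self.SIZES, n_perm=50, seed=1,
                                         mode="genome")
        assert 0 < res.p_value <= 1


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({"cell_type": ["CELL"] * len(samples)}, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


class TestCorrelation:
    def test_identity_and_negation(self):
        x = np.array([1.0, 5.0, 2.0, 9.0, 3.0])
        em = _expr([x, x, x.max() - x + 0.5])
        assert expression_correlation(em, "G0", "G1", transform="none") == pytest.approx(1.0)
        assert expression_correlation(em, "G0", "G2", transform="none") == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self):
        em = _expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero variance"):
            assert math.isnan(expression_correlation(em, "G0", "G1"))

    def test_too_few_samples_rejected(self):
        em = _expr([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            expression_correlation(em, "G0", "G1")


class TestRanking:
    def test_sorted_by_descending_score(self):
        em = _expr(np.vstack([
            [1, 2, 3, 4, 5],
            [1.1, 2.2, 2.9, 4.2, 5.1],   # high positive r
            [5, 4, 3.2, 2, 1.1],         # negative r
            [1, 3, 2, 5, 4],             # moderate r
        ]).astype(float), genes=["L", "A", "B", "C"])
        ranked = rank_genes_for_lincrna(em, "L", ["A", "B", "C"])
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        assert ranked[0][0] == "A" and ranked[-1][0] == "B"

    def test_ties_break_lexicographically(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        em = _expr([x, 2 * x, 3 * x, 4 * x], genes=["L", "Z", "A", "M"])
        ranked = rank_genes_for_lincrna(em, "L", ["Z", "A", "M"], transform="none")
        assert [g for g, _ in ranked] == ["A", "M", "Z"]  # all r = 1.0

    def test_order_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(2, 1, size=(6, 30))
        em1 = _expr(base, genes=["L", "A", "B", "C", "D", "E"])
        # common strictly monotone transform of all expression values
        em2 = _expr(base ** 1.7 * 3, genes=["L", "A", "B", "C", "D", "E"])
        r1 = [g for g, _ in rank_genes_for_lincrna(em1, "L", list("ABCDE"),
                                                   method="spearman")]
        r2 = [g for g, _ in rank_genes_for_lincrna(em2, "L", list("ABCDE"),
                                                   method="spearman")]
        assert r1 == r2


class TestGsea:
    def test_es_matches_hand_oracle_top_block(self):
        # equal scores: hits at the top of a 10-gene list
        ranked = [(f"G{i}", 1.0) for i in range(10)]
        sets = {"T": {"G0", "G1", "G2", "G3", "G4"}}
        out = gsea_preranked(ranked, sets, weight_p=1.0, n_perm=50, seed=0,
                             min_size=3)
        scores = [1.0] * 10
        hits = [i < 5 for i in range(10)]
        assert out[0].es == pytest.approx(brute_force_es(scores, hits, 1.0),
                                          abs=1e-12)

    def test_set_outside_list_skipped_with_warning(self):
        ranked = [(f"G{i}", float(10 - i)) for i in range(10)]
        with pytest.warns(UserWarning, match="no members"):
            out = gsea_preranked(ranked, {"T": {"X1", "X2"}}, n_perm=10, seed=0)
        assert out == []

    def test_universe_set_rejected(self):
        ranked = [(f"G{i}", float(10 - i)) for i in range(10)]
        with pytest.raises(ValueError, match="universe"):
            gsea_preranked(ranked, {"T": {f"G{i}" for i in range(10)}},
                           n_perm=10, seed=0, min_size=3)

    def test_reversed_symmetric_ranking_flips_es_sign_at_p0(self):
        n = 12
        scores = np.linspace(1, -1, n)
        genes = [f"G{i}" for i in range(n)]
        hit = {"G0", "G1", "G4"}
        fwd = [(g, s) for g, s in zip(genes, scores)]
        rev = [(g, s) for g, s in zip(genes[::-1], scores)]
        es_f = gsea_preranked(fwd, {"T": hit}, weight_p=0.0, n_perm=10,
                              seed=0, min_size=2)[0].es
        es_r = gsea_preranked(rev, {"T": hit}, weight_p=0.0, n_perm=10,
                              seed=0, min_size=2)[0].es
        assert es_f == pytest.approx(-es_r, abs=1e-12)


class TestAssociationMatrix:
    @staticmethod
    def _result(term, nes, q):
        return GseaResult(term, math.copysign(0.5, nes), nes, 0.001, q, 10)

    def test_identical_rows_one_cluster(self):
        res = {f"L{i}": [self._result("T1", 2.0, 0.001),
                         self._result("T2", -2.0, 0.001)] for i in range(6)}
        m = build_association_matrix(res, k=2, seed=0)
        assert len(set(m.row_clusters.values())) == 1

    def test_block_pattern_recovered(self):
        res = {}
        for i in range(5):
            res[f"A{i}"] = [self._result("T1", 2.0, 1e-4)]
            res[f"B{i}"] = [self._result("T2", 2.0, 1e-4)]
        m = build_association_matrix(res, k=2, seed=0)
        a_labels = {m.row_clusters[f"A{i}"] for i in range(5)}
        b_labels = {m.row_clusters[f"B{i}"] for i in range(5)}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_non_significant_entries_zero(self):
        res = {f"L{i}": [self._result("T1", 2.0, 0.5),
                         self._result("T2", 2.0, 0.001)] for i in range(3)}
        m = build_association_matrix(res, k=2, seed=0)
        assert (m.values["T1"] == 0).all()
        assert (m.values["T2"] > 0).all()

    def test_too_few_rows_rejected(self):
        res = {"L1": [self._result("T1", 2.0, 0.001)]}
        with pytest.raises(ValueError, match="k-means"):
            build_association_matrix(res, k=5, seed=0)


class TestHypergeometricEnrichment:
    @staticmethod
    def closed_form_tail(n_o, n_u, n_t, n_c):
        total = math.comb(n_u, n_c)
        return sum(
            math.comb(n_t, k) * math.comb(n_u - n_t, n_c - k)
            for k in range(n_o, min(n_t, n_c) + 1)
        ) / total

    def test_community_equals_term(self):
        term = {f"G{i}" for i in range(10)}
        universe = term | {f"H{i}" for i in range(10)}
        df = enrich_community(term, universe, {"T": term})
        assert df.loc[0, "p_value"] == pytest.approx(
            self.closed_form_tail(10, 20, 10, 10)
        )

    def test_disjoint_term_p_one(self):
        community = {f"G{i}" for i in range(5)}
        universe = community | {f"H{i}" for i in range(10)}
        df = enrich_community(community, universe, {"T": {f"H{i}" for i in range(4)}})
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_community_is_universe(self):
        universe = {f"G{i}" for i in range(8)}
        df = enrich_community(universe, universe,
                              {"T1": {f"G{i}" for i in range(3)}})
        assert df["p_value"].tolist() == pytest.approx([1.0])

    def test_matches_closed_form_over_random_parameters(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n_u = int(rng.integers(5, 50))
            universe = {f"G{i}" for i in range(n_u)}
            n_c = int(rng.integers(1, n_u + 1))
            n_t = int(rng.integers(1, n_u + 1))
            community = set(list(universe)[:n_c])
            term = set(rng.choice(sorted(universe), size=n_t, replace=False))
            df = enrich_community(community, universe, {"T": term})
            n_o = len(term & community)
            assert df.loc[0, "p_value"] == pytest.approx(
                self.closed_form_tail(n_o, n_u, n_t, n_c), rel=1e-10
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_community(set(), set(), {"T": {"G"}})


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        a = list(range(30))
        _, p = compare_groups(a, a)
        assert p > 0.9

    def test_separated_groups_highly_significant(self):
        a = list(np.arange(20, dtype=float))
        b = list(np.arange(100, 120, dtype=float))
        _, p = compare_groups(a, b)
        assert p < 1e-6

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.7, 1, 25)
        _, p1 = compare_groups(a, b)
        f = lambda x: np.exp(3 * x) + 5  # strictly increasing
        _, p2 = compare_groups(f(a), f(b))
        assert p1 == pytest.approx(p2)
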