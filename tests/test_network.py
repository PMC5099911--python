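"""ChIN construction, descriptors, communities, k-hop queries."""

import networkx as nx
import numpy as np
import pytest

from linc_chin.intervals import GenomicInterval
from linc_chin.io import GeneRecord, InteractionCluster
from linc_chin.network import (
    build_chin,
    compute_descriptors,
    detect_communities,
    extract_gene_subnetwork,
    fit_powerlaw_discrete,
    gene_pair_distance,
    k_hop_neighborhood,
    write_graphml,
)


def iv(chrom, s, e):
    return GenomicInterval(chrom, s, e)


class TestBuildChin:
    def test_minimal_graph_two_dres(self):
        chin = build_chin(
            [InteractionCluster(iv("chr1", 100, 200), iv("chr1", 5000, 5100))], {}
        )
        assert chin.n_nodes == 2 and chin.n_edges == 1
        assert all(n.role == "dre" for n in chin.nodes.values())
        assert chin.graph[0][1]["weight"] == 1

    def test_overlapping_anchors_merge(self):
        # two clusters whose left anchors overlap: one merged left node, 2 edges
        clusters = [
            InteractionCluster(iv("chr1", 100, 300), iv("chr1", 10000, 10100)),
            InteractionCluster(iv("chr1", 200, 400), iv("chr1", 20000, 20100)),
        ]
        chin = build_chin(clusters, {})
        assert chin.n_nodes == 3 and chin.n_edges == 2
        assert chin.node_region(0) == iv("chr1", 100, 400)

    def test_self_loop_cluster_dropped(self):
        promoters = {"G1": [iv("chr1", 0, 5000)]}
        clusters = [
            InteractionCluster(iv("chr1", 100, 200), iv("chr1", 300, 400)),
            InteractionCluster(iv("chr1", 9000, 9100), iv("chr1", 9050, 9200)),
        ]
        chin = build_chin(clusters, promoters)
        # first cluster: both anchors merge? no (gap 100) -> two nodes + edge;
        # second: anchors overlap into one node -> self loop dropped
        assert chin.n_edges == 1
        merged = [n for n in chin.nodes.values() if n.region == iv("chr1", 9000, 9200)]
        assert len(merged) == 1

    def test_parallel_clusters_collapse_with_weight(self):
        c = InteractionCluster(iv("chr1", 100, 200), iv("chr1", 5000, 5100), 4)
        chin = build_chin([c, c, c], {})
        assert chin.n_edges == 1
        assert chin.graph[0][1]["weight"] == 3
        assert chin.graph[0][1]["total_pet"] == 12

    def test_promoter_role_requires_one_bp(self):
        promoters = {"G1": [iv("chr1", 0, 100)]}
        chin = build_chin(
            [InteractionCluster(iv("chr1", 99, 200), iv("chr1", 5000, 5100))],
            promoters,
        )
        assert chin.nodes[0].role == "promoter" and chin.nodes[0].gene_ids == ("G1",)
        # abutting window (no shared base) stays DRE
        chin2 = build_chin(
            [InteractionCluster(iv("chr1", 100, 200), iv("chr1", 5000, 5100))],
            promoters,
        )
        assert chin2.nodes[0].role == "dre"

    def test_node_regions_disjoint_on_desk_data(self, desk_chin):
        regions = sorted(
            (n.region for n in desk_chin.nodes.values()),
            key=lambda r: (r.chrom, r.start),
        )
        for a, b in zip(regions, regions[1:]):
            assert a.chrom != b.chrom or a.end <= b.start


class TestDescriptors:
    def test_triangle(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1, "weight")
        d = compute_descriptors(g)
        assert d.transitivity == 1.0 and d.graph_density == 1.0

    def test_star_betweenness(self):
        g = nx.star_graph(5)  # center 0, 5 leaves
        d = compute_descriptors(g)
        assert d.betweenness[0] == 10.0  # C(5,2) leaf pairs route via center
        assert all(d.degree_distribution[k] == v for k, v in {1: 5, 5: 1}.items())

    def test_degree_distribution_sums_to_twice_edges(self, desk_chin):
        d = compute_descriptors(desk_chin)
        assert sum(k * v for k, v in d.degree_distribution.items()) == 2 * d.n_edges
        assert sum(d.degree_distribution.values()) == d.n_nodes
        assert 0 <= d.graph_density <= 1

    def test_uniform_degrees_yield_no_exponent(self):
        assert fit_powerlaw_discrete([3, 3, 3, 3]) is None

    def test_configuration_model_exponent_recovered(self):
        from linc_chin.synthetic import make_powerlaw_graph

        g = make_powerlaw_graph(5000, 2.5, seed=42)
        fit = fit_powerlaw_discrete([d for _, d in g.degree()])
        assert fit is not None
        assert abs(fit.alpha - 2.5) <= 0.3


class TestCommunities:
    def test_two_cliques_split_on_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
        g.add_edge(0, 10)
        nx.set_edge_attributes(g, 1, "weight")
        comm = detect_communities(g, seed=0, min_size=5)
        assert comm.n_communities == 2
        assert comm.labels[0] != comm.labels[10]
        assert sorted(comm.sizes.values()) == [10, 10]

    def test_single_node_and_edgeless(self):
        g1 = nx.Graph()
        g1.add_node(0)
        assert detect_communities(g1).n_communities == 1
        gn = nx.empty_graph(7)
        assert detect_communities(gn).n_communities == 7

    def test_partition_and_modularity_beats_trivial(self):
        g = nx.planted_partition_graph(3, 12, 0.9, 0.02, seed=4)
        nx.set_edge_attributes(g, 1, "weight")
        comm = detect_communities(g, seed=0)
        assert sorted(comm.labels) == sorted(g.nodes)  # every node exactly once
        parts = [set(comm.members(l)) for l in comm.sizes]
        q = nx.community.modularity(g, parts)
        q_trivial = nx.community.modularity(g, [set(g.nodes)])
        assert q >= q_trivial


class TestKHop:
    def test_k0_is_seed_set(self, desk_chin):
        seed = next(iter(desk_chin.nodes))
        assert k_hop_neighborhood(desk_chin, [seed], 0) == {seed}

    def test_path_graph(self):
        g = nx.path_graph(5)  # a-b-c-d-e
        assert k_hop_neighborhood(g, [0], 3) == {0, 1, 2, 3}

    def test_isolated_seed(self):
        g = nx.empty_graph(3)
        assert k_hop_neighborhood(g, [1], 4) == {1}

    def test_unknown_seed_named(self):
        with pytest.raises(KeyError, match="99"):
            k_hop_neighborhood(nx.path_graph(3), [99], 1)

    def test_monotone_in_k_and_matches_reachability(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(2, 50))
            g = nx.gnp_random_graph(n, 0.1, seed=int(rng.integers(2**31)))
            seed = int(rng.integers(0, n))
            adj = nx.to_numpy_array(g, dtype=bool)
            reach = np.zeros(n, dtype=bool)
            reach[seed] = True
            prev = set()
            for k in range(5):
                got = k_hop_neighborhood(g, [seed], k)
                expected = set(np.flatnonzero(reach))
                assert got == expected
                assert prev <= got
                prev = got
                reach = reach | (adj @ reach)


class TestGeneSubnetwork:
    @staticmethod
    def _fixture():
        genes = {
            "L1": GeneRecord("L1", "L1", "lincRNA", GenomicInterval("chr1", 100, 2000, "+"), (100,)),
            "P1": GeneRecord("P1", "P1", "protein_coding", GenomicInterval("chr1", 10000, 12000, "+"), (10000,)),
            "P2": GeneRecord("P2", "P2", "protein_coding", GenomicInterval("chr1", 12500, 14000, "+"), (12500,)),
        }
        promoters = {
            "L1": [iv("chr1", 0, 2600)],
            "P1": [iv("chr1", 7500, 12500)],
            "P2": [iv("chr1", 10000, 15000)],
        }
        clusters = [
            InteractionCluster(iv("chr1", 50, 400), iv("chr1", 11000, 11400))
        ]
        return genes, build_chin(clusters, promoters)

    def test_node_with_two_genes_yields_all_pairs(self):
        genes, chin = self._fixture()
        pairs = extract_gene_subnetwork(chin, genes, "lincRNA", "protein_coding")
        assert pairs == [("L1", "P1"), ("L1", "P2")]

    def test_no_cross_biotype_edges(self):
        genes, chin = self._fixture()
        assert extract_gene_subnetwork(chin, genes, "miRNA", "protein_coding") == []

    def test_matches_brute_force_on_desk_data(self, desk_chin, desk_genes):
        pairs = set(
            extract_gene_subnetwork(desk_chin, desk_genes, "lincRNA", "protein_coding")
        )
        brute = set()
        for u, v, in desk_chin.graph.edges():
            for x, y in ((u, v), (v, u)):
                for ga in desk_chin.genes_on_node(x):
                    for gb in desk_chin.genes_on_node(y):
                        if (
                            desk_genes[ga].biotype == "lincRNA"
                            and desk_genes[gb].biotype == "protein_coding"
                        ):
                            brute.add((ga, gb))
        assert pairs == brute


class TestGenePairDistance:
    def test_arithmetic(self):
        genes = {
            "A": GeneRecord("A", "A", "lincRNA", GenomicInterval("chr1", 10000, 12000, "+"), (10000,)),
            "B": GeneRecord("B", "B", "protein_coding", GenomicInterval("chr1", 110000, 115000, "+"), (110000,)),
        }
        assert gene_pair_distance(("A", "B"), genes) == 100000
        assert gene_pair_distance(("A", "A"), genes) == 0

    def test_interchromosomal_flagged(self):
        genes = {
            "A": GeneRecord("A", "A", "lincRNA", GenomicInterval("chr1", 0, 100, "+"), (0,)),
            "B": GeneRecord("B", "B", "lincRNA", GenomicInterval("chr2", 0, 100, "+"), (0,)),
        }
        assert gene_pair_distance(("A", "B"), genes) is None

    def test_planted_distances_recovered(self, desk_sim, desk_genes):
        for pair in desk_sim.manifest.pairs:
            if pair["distance"] is None:
                continue
            got = gene_pair_distance((pair["lincrna"], pair["partner"]), desk_genes)
            assert got == pair["distance"]


def test_graphml_round_trip(desk_chin, tmp_path):
    path = tmp_path / "chin.graphml"
    write_graphml(desk_chin, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == desk_chin.n_nodes
    assert g.number_of_edges() == desk_chin.n_edges
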