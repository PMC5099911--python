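"""Chromatin interaction network (ChIN) construction and analysis.

Nodes are merged ChIA-PET anchor regions; a node is a *promoter* node
when it overlaps (>= 1 bp) the promoter window of at least one annotated
gene, otherwise it is a distal regulatory element (DRE).  Edges record
observed chromatin contacts between node pairs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from intervaltree import IntervalTree
from scipy import optimize, special

from .intervals import GenomicInterval, merge_intervals
from .io import GeneRecord, InteractionCluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChINNode:
    node_id: int
    region: GenomicInterval
    role: str  # "promoter" | "dre"
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.role == "promoter") != bool(self.gene_ids):
            raise ValueError("role is 'promoter' iff gene_ids is non-empty")


class ChIN:
    """The chromatin interaction network: a simple weighted graph.

    Parallel interaction clusters between one node pair collapse into a
    single edge whose ``weight`` counts clusters and ``total_pet`` sums
    their PET support.  Self-loop clusters (both anchors inside one
    merged node) are excluded.
    """

    def __init__(self, nodes: Sequence[ChINNode], graph: nx.Graph) -> None:
        self.nodes: dict[int, ChINNode] = {n.node_id: n for n in nodes}
        self.graph = graph
        self._gene_nodes: dict[str, list[int]] = {}
        for n in nodes:
            for g in n.gene_ids:
                self._gene_nodes.setdefault(g, []).append(n.node_id)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_region(self, node_id: int) -> GenomicInterval:
        return self.nodes[node_id].region

    def genes_on_node(self, node_id: int) -> tuple[str, ...]:
        return self.nodes[node_id].gene_ids

    def nodes_of_gene(self, gene_id: str) -> list[int]:
        """Promoter nodes overlapping the gene's promoter windows."""
        return list(self._gene_nodes.get(gene_id, []))

    def gene_ids(self) -> list[str]:
        return sorted(self._gene_nodes)

    def dre_nodes(self) -> list[int]:
        return [i for i, n in sorted(self.nodes.items()) if n.role == "dre"]

    def promoter_nodes(self) -> list[int]:
        return [i for i, n in sorted(self.nodes.items()) if n.role == "promoter"]

    def neighbors(self, node_id: int) -> list[int]:
        return sorted(self.graph.neighbors(node_id))


def build_chin(
    clusters: Sequence[InteractionCluster],
    promoters: Mapping[str, Sequence[GenomicInterval]],
    max_gap: int = 0,
) -> ChIN:
    """Build the ChIN from interaction clusters and promoter windows.

    Anchors are merged (gap <= ``max_gap``) into node regions; each
    cluster adds/weights the edge between the nodes containing its two
    anchors.  Node role comes from >= 1 bp promoter-window overlap.
    """
    if not clusters:
        raise ValueError("cannot build a ChIN from zero interaction clusters")
    anchors = []
    for c in clusters:
        anchors.append(c.anchor_a)
        anchors.append(c.anchor_b)
    regions = merge_intervals(anchors, max_gap=max_gap)

    trees: dict[str, IntervalTree] = {}
    nodes_raw: list[GenomicInterval] = []
    for node_id, region in enumerate(regions):
        nodes_raw.append(region)
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, node_id
        )

    def locate(iv: GenomicInterval) -> int:
        hits = trees[iv.chrom].overlap(iv.start, iv.end)
        assert len(hits) == 1, f"anchor {iv} not contained in exactly one merged node"
        return next(iter(hits)).data

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes_raw)))
    n_dropped = 0
    for c in clusters:
        u, v = locate(c.anchor_a), locate(c.anchor_b)
        if u == v:
            n_dropped += 1
            continue
        if graph.has_edge(u, v):
            graph[u][v]["weight"] += 1
            graph[u][v]["total_pet"] += c.pet_count
        else:
            graph.add_edge(u, v, weight=1, total_pet=c.pet_count)
    if n_dropped:
        logger.info("dropped %d self-loop clusters (both anchors in one node)", n_dropped)

    # promoter-overlap role assignment
    promoter_trees: dict[str, IntervalTree] = {}
    for gene_id, windows in promoters.items():
        for w in windows:
            promoter_trees.setdefault(w.chrom, IntervalTree()).addi(
                w.start, w.end, gene_id
            )
    nodes: list[ChINNode] = []
    for node_id, region in enumerate(nodes_raw):
        tree = promoter_trees.get(region.chrom)
        gene_ids: tuple[str, ...] = ()
        if tree is not None:
            gene_ids = tuple(sorted({h.data for h in tree.overlap(region.start, region.end)}))
        role = "promoter" if gene_ids else "dre"
        nodes.append(ChINNode(node_id, region, role, gene_ids))
    return ChIN(nodes, graph)


# ---------------------------------------------------------------------------
# Descriptors


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int


@dataclass
class NetworkDescriptors:
    n_nodes: int
    n_edges: int
    degree_distribution: dict[int, int]
    power_law: PowerLawFit | None
    kcore_distribution: dict[int, int]
    transitivity: float
    graph_density: float
    betweenness: dict[int, float]
    closeness: dict[int, float]
    component_sizes: list[int]


def fit_powerlaw_discrete(
    values: Sequence[int], xmin: int | None = None
) -> PowerLawFit | None:
    """Fit P(x) ~ x^-alpha to discrete data by maximum likelihood.

    When ``xmin`` is not given it is selected by minimizing the
    Kolmogorov-Smirnov distance between the empirical tail and the
    fitted zeta model over candidate xmin values.  Returns None when the
    tail is degenerate (fewer than two distinct values).
    """
    x = np.asarray([v for v in values if v >= 1], dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        return None

    def mle_alpha(tail: np.ndarray, xm: int) -> float:
        slog = np.log(tail).sum()
        n = tail.size

        # negative log-likelihood: n*log(zeta(a, xm)) + a*sum(log x)
        def nll(a: float) -> float:
            return n * np.log(special.zeta(a, xm)) + a * slog

        res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
        return float(res.x)

    def ks_distance(tail: np.ndarray, xm: int, alpha: float) -> float:
        xs = np.unique(tail)
        emp = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
        # model CDF at integer x: 1 - zeta(alpha, x+1)/zeta(alpha, xmin)
        z0 = special.zeta(alpha, xm)
        model = 1.0 - special.zeta(alpha, xs + 1) / z0
        return float(np.max(np.abs(emp - model)))

    candidates = (
        [int(xmin)] if xmin is not None else sorted({int(v) for v in np.unique(x)})[:-1]
    )
    best: PowerLawFit | None = None
    for xm in candidates:
        tail = x[x >= xm]
        if tail.size < 10 and xmin is None and best is not None:
            continue
        if np.unique(tail).size < 2:
            continue
        alpha = mle_alpha(tail, xm)
        ks = ks_distance(tail, xm, alpha)
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha, xm, ks, int(tail.size))
    return best


def compute_descriptors(chin: ChIN | nx.Graph) -> NetworkDescriptors:
    """Compute the standard graph descriptors of a ChIN."""
    graph = chin.graph if isinstance(chin, ChIN) else chin
    if graph.number_of_nodes() == 0:
        raise ValueError("descriptors of an empty graph are undefined")
    degrees = [d for _, d in graph.degree()]
    degree_distribution = dict(sorted(Counter(degrees).items()))
    power_law = fit_powerlaw_discrete(degrees)
    kcore = Counter(nx.core_number(graph).values())
    component_sizes = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    return NetworkDescriptors(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        degree_distribution=degree_distribution,
        power_law=power_law,
        kcore_distribution=dict(sorted(kcore.items())),
        transitivity=float(nx.transitivity(graph)),
        graph_density=float(nx.density(graph)),
        betweenness=nx.betweenness_centrality(graph, normalized=False),
        closeness=nx.closeness_centrality(graph),
        component_sizes=component_sizes,
    )


# ---------------------------------------------------------------------------
# Communities


@dataclass
class CommunityAssignment:
    labels: dict[int, int]  # node_id -> community label
    sizes: dict[int, int]  # label -> node count
    min_size: int

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    def large_communities(self) -> list[int]:
        """Labels of communities meeting the size floor for enrichment."""
        return sorted(l for l, s in self.sizes.items() if s >= self.min_size)

    def members(self, label: int) -> list[int]:
        return sorted(n for n, l in self.labels.items() if l == label)


def detect_communities(
    chin: ChIN | nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    min_size: int = 20,
) -> CommunityAssignment:
    """Weighted modularity (Louvain) community detection.

    Deterministic for a given seed; community labels are assigned in
    order of each community's smallest node id.
    """
    graph = chin.graph if isinstance(chin, ChIN) else chin
    if graph.number_of_nodes() == 0:
        return CommunityAssignment({}, {}, min_size)
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=min)
    labels = {n: i for i, c in enumerate(comms) for n in c}
    sizes = {i: len(c) for i, c in enumerate(comms)}
    return CommunityAssignment(labels, sizes, min_size)


# ---------------------------------------------------------------------------
# Neighborhoods and gene-level views


def k_hop_neighborhood(
    chin: ChIN | nx.Graph, seed_nodes: Iterable[int], k: int
) -> set[int]:
    """All nodes within shortest-path distance <= k of any seed (seeds included)."""
    graph = chin.graph if isinstance(chin, ChIN) else chin
    if k < 0:
        raise ValueError("k must be >= 0")
    seeds = list(seed_nodes)
    for s in seeds:
        if s not in graph:
            raise KeyError(f"seed node {s} not in graph")
    out: set[int] = set()
    for s in seeds:
        out.update(nx.single_source_shortest_path_length(graph, s, cutoff=k))
    return out


def extract_gene_subnetwork(
    chin: ChIN,
    genes: Mapping[str, GeneRecord],
    biotype_a: str,
    biotype_b: str,
) -> list[tuple[str, str]]:
    """Gene-pair edges joining a biotype_a gene to a biotype_b gene.

    A ChIN edge between a node carrying biotype_a genes and a node
    carrying biotype_b genes yields all cross pairs, the a-side gene
    first.  Pairs are deduplicated and sorted.
    """
    pairs: set[tuple[str, str]] = set()
    for u, v in chin.graph.edges():
        for x, y in ((u, v), (v, u)):
            a_genes = [g for g in chin.genes_on_node(x)
                       if g in genes and genes[g].biotype == biotype_a]
            b_genes = [g for g in chin.genes_on_node(y)
                       if g in genes and genes[g].biotype == biotype_b]
            for ga in a_genes:
                for gb in b_genes:
                    if ga != gb:
                        pairs.add((ga, gb))
    return sorted(pairs)


def gene_pair_degrees(pairs: Sequence[tuple[str, str]]) -> tuple[Counter, Counter]:
    """Distinct-partner counts for the left and right columns of a pair list."""
    left: dict[str, set[str]] = {}
    right: dict[str, set[str]] = {}
    for a, b in pairs:
        left.setdefault(a, set()).add(b)
        right.setdefault(b, set()).add(a)
    return (
        Counter({g: len(p) for g, p in left.items()}),
        Counter({g: len(p) for g, p in right.items()}),
    )


def gene_pair_distance(
    pair: tuple[str, str], genes: Mapping[str, GeneRecord]
) -> int | None:
    """|TSS_a - TSS_b| using canonical (5'-most) TSSs; None when inter-chromosomal."""
    a, b = genes[pair[0]], genes[pair[1]]
    if a.chrom != b.chrom:
        return None
    return abs(a.canonical_tss - b.canonical_tss)


# ---------------------------------------------------------------------------
# Serialization


def write_graphml(chin: ChIN, path) -> None:
    g = nx.Graph()
    for node_id, node in sorted(chin.nodes.items()):
        g.add_node(
            node_id,
            region=str(node.region),
            role=node.role,
            gene_ids=",".join(node.gene_ids),
        )
    for u, v, data in chin.graph.edges(data=True):
        g.add_edge(u, v, weight=data["weight"], total_pet=data["total_pet"])
    nx.write_graphml(g, path)
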