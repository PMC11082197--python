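"""Bipartite module detection on the DC network via Louvain modularity.

Each DC network node is a (gene, region) pair; edges only cross regions.
Standard Newman modularity on this bipartite graph is maximized with the
Louvain heuristic (seeded for reproducibility), matching the common practice
of running a general-graph community routine on a two-layered network rather
than a bipartite-specific objective. Modules are relabelled deterministically
by descending size (ties by smallest member node id), flagged by the
20-gene minimum used for enrichment, and mirrored by structure-preserving
random modules that supply the enrichment null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import ValidationError
from .network import DCNetwork

logger = logging.getLogger(__name__)


def node_name(gene: str, region: str) -> str:
    return f"{gene}@{region}"


def build_bipartite_graph(network: DCNetwork, weighted: bool = False) -> nx.Graph:
    """DC edge list -> undirected bipartite graph of (gene, region) nodes.

    Node attributes carry ``gene`` and ``region``; with ``weighted`` the
    edge weight is |z|. Insertion order is sorted so identical edge lists
    give identical graphs.
    """
    g = nx.Graph()
    r1, r2 = network.region_pair
    edges = network.edges.sort_values(["gene_a", "gene_b"])
    for row in edges.itertuples():
        a = node_name(row.gene_a, r1)
        b = node_name(row.gene_b, r2)
        if a == b:
            raise ValidationError(f"self-loop at {a}")
        g.add_node(a, gene=row.gene_a, region=r1)
        g.add_node(b, gene=row.gene_b, region=r2)
        if weighted:
            g.add_edge(a, b, weight=abs(float(row.z)))
        else:
            g.add_edge(a, b)
    return g


@dataclass
class ModulePartition:
    """A node -> module assignment with its Newman modularity score."""

    assignment: dict[str, int]
    modularity: float
    modules: dict[int, dict[str, set[str]]]  # module id -> region -> gene set
    size_pass: dict[int, bool] = field(default_factory=dict)

    def module_size(self, module_id: int) -> int:
        return sum(len(s) for s in self.modules[module_id].values())

    def passing_modules(self) -> list[int]:
        return [m for m, ok in sorted(self.size_pass.items()) if ok]


def recompute_modularity(
    graph: nx.Graph, assignment: dict[str, int], weighted: bool = False
) -> float:
    """Newman modularity of an assignment, recomputed from scratch."""
    comms: dict[int, set] = {}
    for node, mod in assignment.items():
        comms.setdefault(mod, set()).add(node)
    return nx.community.modularity(
        graph, comms.values(), weight="weight" if weighted else None
    )


def louvain_partition(graph: nx.Graph, seed: int = 0, weighted: bool = False) -> ModulePartition:
    """Seeded Louvain partition with deterministic module relabelling."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot partition an empty graph")
    weight = "weight" if weighted else None
    comms = nx.community.louvain_communities(graph, weight=weight, seed=seed)
    # relabel by descending size, ties by smallest member node id
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignment = {node: mid for mid, comm in enumerate(ordered, start=1) for node in comm}
    q = nx.community.modularity(graph, ordered, weight=weight)
    modules: dict[int, dict[str, set[str]]] = {}
    for mid, comm in enumerate(ordered, start=1):
        per_region: dict[str, set[str]] = {}
        for node in comm:
            data = graph.nodes[node]
            per_region.setdefault(data.get("region", ""), set()).add(
                data.get("gene", node)
            )
        modules[mid] = per_region
    logger.info("Louvain: %d modules, Q=%.4f", len(modules), q)
    return ModulePartition(assignment=assignment, modularity=float(q), modules=modules)


def filter_modules(partition: ModulePartition, min_genes: int = 20) -> ModulePartition:
    """Flag modules meeting the minimum total gene count; nothing re-clusters."""
    for mid in partition.modules:
        partition.size_pass[mid] = partition.module_size(mid) >= min_genes
    n_pass = sum(partition.size_pass.values())
    if n_pass == 0:
        logger.warning("no module reaches the %d-gene minimum", min_genes)
    return partition


def random_modules(
    background_genes_per_region: dict[str, list[str]],
    module_structure: dict[int, dict[str, int]],
    n_perm: int = 10,
    seed: int = 0,
) -> list[dict[int, dict[str, set[str]]]]:
    """Structure-preserving random modules from the background gene lists.

    For each permutation and each region side, module-id labels are shuffled
    over the background genes so the multiset of module sizes per side is
    exactly preserved. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    for region, genes in background_genes_per_region.items():
        need = sum(sizes.get(region, 0) for sizes in module_structure.values())
        if need > len(genes):
            raise ValidationError(
                f"background for {region} ({len(genes)}) smaller than required ({need})"
            )
    perms = []
    for _ in range(n_perm):
        perm: dict[int, dict[str, set[str]]] = {m: {} for m in module_structure}
        for region, genes in background_genes_per_region.items():
            shuffled = list(genes)
            rng.shuffle(shuffled)
            pos = 0
            for mid in sorted(module_structure):
                k = module_structure[mid].get(region, 0)
                perm[mid][region] = set(shuffled[pos : pos + k])
                pos += k
        perms.append(perm)
    return perms


class LouvainBipartitePartitioner(BaseEstimator):
    """sklearn-style wrapper: fit on a DCNetwork, expose the partition.

    Attributes
    ----------
    graph_ : networkx.Graph
    partition_ : ModulePartition
        With ``size_pass`` flags already set from ``min_genes``.
    """

    def __init__(self, seed: int = 0, weighted: bool = False, min_genes: int = 20):
        self.seed = seed
        self.weighted = weighted
        self.min_genes = min_genes

    def fit(self, network: DCNetwork, y=None):
        self.graph_ = build_bipartite_graph(network, weighted=self.weighted)
        self.partition_ = filter_modules(
            louvain_partition(self.graph_, seed=self.seed, weighted=self.weighted),
            min_genes=self.min_genes,
        )
        self.modularity_ = self.partition_.modularity
        return self
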