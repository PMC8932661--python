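"""Community decomposition of the candidate LR graph.

The candidate graph is partitioned by Louvain modularity maximization into
"within" communities (WC) whose size is capped at the cohort sample size, so
that each community's precision matrix is estimable.  Edges crossing two
within-communities are collected into "between" pseudocommunities (BC) so
that every candidate edge is regularized in exactly one context.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import EdgeKey, LRGraph, LRNode

logger = logging.getLogger(__name__)

WITHIN = "within"
BETWEEN = "between"


@dataclass
class Community:
    id: str
    kind: str  # within | between
    nodes: frozenset[LRNode]
    candidate_edges: frozenset[EdgeKey]
    parent_pair: tuple[str, str] | None = None
    unsplittable: bool = False
    level: int = 0

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class CommunityPartition:
    communities: list[Community]  # within-communities only
    seed: int
    max_size: int
    modularity_trace: list[float] = field(default_factory=list)

    @property
    def node_map(self) -> dict[LRNode, str]:
        out: dict[LRNode, str] = {}
        for c in self.communities:
            for node in c.nodes:
                out[node] = c.id
        return out


def modularity(graph: LRGraph | nx.Graph, partition: dict[LRNode, int | str],
               weight_mode: str = "abs_pearson") -> float:
    """Newman modularity Q of a node partition on nonnegative edge weights.

    Q = (1/2m) sum_vw [A_vw - k_v k_w / 2m] delta(c_v, c_w) with m the total
    edge weight and k the weighted degree.
    """
    g = graph.to_networkx(weight_mode) if isinstance(graph, LRGraph) else graph
    if g.number_of_edges() == 0:
        raise ValueError("modularity of an empty graph is undefined")
    m = g.size(weight="weight")
    if m <= 0:
        raise ValueError("total edge weight must be positive")
    degree = dict(g.degree(weight="weight"))
    q = 0.0
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        if w < 0:
            raise ValueError("modularity requires nonnegative weights")
        if partition[u] == partition[v]:
            q += w / m  # A_vw counted for both (v,w) and (w,v)
    for comm in set(partition.values()):
        k_c = sum(k for node, k in degree.items() if partition[node] == comm)
        q -= (k_c / (2.0 * m)) ** 2
    return q


def _louvain(g: nx.Graph, seed: int) -> list[set[LRNode]]:
    return [set(c) for c in nx.community.louvain_communities(g, weight="weight", seed=seed)]


def detect_within_communities(
    graph: LRGraph,
    max_size: int | None = None,
    seed: int = 0,
    max_depth: int = 10,
    weight_mode: str = "abs_pearson",
) -> CommunityPartition:
    """Hierarchical Louvain partition with a hard size cap.

    Communities larger than ``max_size`` (default: the sample size) are
    recursively re-partitioned on their induced subgraph.  If Louvain cannot
    split a group further (single community returned) or the recursion depth
    is exhausted, the group is kept and flagged ``unsplittable``.
    Deterministic for a fixed seed.
    """
    if not graph.edges:
        raise ValueError("cannot partition an empty graph")
    if max_size is None:
        max_size = graph.n_samples
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    g = graph.to_networkx(weight_mode)

    final: list[tuple[set[LRNode], int, bool]] = []  # (nodes, level, unsplittable)

    def recurse(sub: nx.Graph, level: int, sub_seed: int) -> None:
        groups = _louvain(sub, sub_seed)
        for k, group in enumerate(groups):
            if len(group) <= max_size:
                final.append((group, level, False))
            elif level + 1 >= max_depth or len(groups) == 1:
                final.append((group, level, True))
            else:
                recurse(sub.subgraph(group).copy(), level + 1,
                        (sub_seed * 31 + k + 1) % (2 ** 31))

    recurse(g, 0, seed)

    communities: list[Community] = []
    edge_lookup = set(graph.edges)
    for i, (nodes, level, unsplit) in enumerate(
            sorted(final, key=lambda t: sorted(n.label() for n in t[0]))):
        internal = frozenset(
            e for e in edge_lookup if e[0] in nodes and e[1] in nodes
        )
        communities.append(Community(
            id=f"wc{i:03d}", kind=WITHIN, nodes=frozenset(nodes),
            candidate_edges=internal, level=level, unsplittable=unsplit,
        ))
    if unflagged := [c for c in communities if c.size > max_size and not c.unsplittable]:
        raise AssertionError(f"size cap violated for {[c.id for c in unflagged]}")
    node_map = {n: c.id for c in communities for n in c.nodes}
    q = modularity(g, node_map)
    logger.info("within-community detection: %d communities (max size %d, Q=%.3f)",
                len(communities), max(c.size for c in communities), q)
    return CommunityPartition(communities=communities, seed=seed,
                              max_size=max_size, modularity_trace=[q])


def build_between_communities(
    graph: LRGraph, partition: CommunityPartition
) -> list[Community]:
    """One pseudocommunity per within-community pair joined by >= 1 edge.

    A BC's nodes are exactly the endpoints of the crossing edges and its
    candidate edges are exactly those crossing edges; single-node BCs are
    never emitted (a crossing edge always contributes two nodes).
    """
    node_map = partition.node_map
    cross: dict[tuple[str, str], list[EdgeKey]] = {}
    for edge in graph.edges:
        lig, rec = edge
        ca, cb = node_map[lig], node_map[rec]
        if ca == cb:
            continue
        key = tuple(sorted((ca, cb)))
        cross.setdefault(key, []).append(edge)
    out: list[Community] = []
    for i, (pair, edges) in enumerate(sorted(cross.items())):
        nodes = frozenset(itertools.chain.from_iterable(edges))
        if len(nodes) < 2:
            continue
        out.append(Community(
            id=f"bc{i:03d}", kind=BETWEEN, nodes=nodes,
            candidate_edges=frozenset(edges), parent_pair=pair,
        ))
    logger.info("built %d between-communities", len(out))
    return out


def write_membership(partition: CommunityPartition, between: list[Community],
                     path) -> None:
    """Flat TSV of node -> community assignments (within + between)."""
    with open(path, "w") as fh:
        fh.write("cell_type\tgene\trole\tcommunity_id\tkind\tlevel\n")
        for comm in list(partition.communities) + list(between):
            for n in sorted(comm.nodes):
                fh.write(f"{n.cell_type}\t{n.gene}\t{n.role}\t"
                         f"{comm.id}\t{comm.kind}\t{comm.level}\n")
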