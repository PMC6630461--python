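"""Classical weighted-graph indices: CPL, network diameter, modularity.

Edge weights are treated directly as path lengths — the networks are
correlation *distances* (w = 1 - r), so a short path means strong coupling.
Shortest-path indices exclude disconnected pairs rather than treating them
as infinite.  Modularity uses the proportion formula

    Mod = sum_{i in M} [ c_ii - (sum_{j in M} c_ij)^2 ]

where c_ij is the proportion of total edge weight running between modules i
and j (within-module weight counts fully toward c_ii, cross-module weight
is split evenly between c_ij and c_ji, so c is symmetric and sums to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .networks import WeightedNetwork

__all__ = ["CommunityPartition", "cpl", "network_diameter", "modularity", "to_networkx"]


@dataclass
class CommunityPartition:
    """Module assignment plus the module-level edge-weight proportion matrix."""

    assignment: dict[str, int]
    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if not np.isclose(c.sum(), 1.0):
            raise ValueError("proportion matrix must sum to 1")
        if not np.allclose(c, c.T):
            raise ValueError("proportion matrix must be symmetric")
        self.c = c


def to_networkx(network: WeightedNetwork) -> nx.Graph:
    """Undirected graph over ROI labels with weight attributes on present edges."""
    g = nx.Graph()
    g.add_nodes_from(network.roi_labels)
    mask = network.edge_mask()
    n = network.n_roi
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                g.add_edge(
                    network.roi_labels[i],
                    network.roi_labels[j],
                    weight=float(network.weights[i, j]),
                )
    return g


def _shortest_path_lengths(network: WeightedNetwork) -> list[float]:
    if network.weights.min() < 0:
        raise ValueError("path-length indices require non-negative weights")
    g = to_networkx(network)
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    lengths: list[float] = []
    for source, targets in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        lengths.extend(d for node, d in targets.items() if node != source)
    return lengths  # one entry per ordered reachable pair


def cpl(network: WeightedNetwork) -> float:
    """Characteristic path length: mean shortest-path distance over connected pairs.

    Pairs in different components (infinite distance) are excluded.
    """
    lengths = _shortest_path_lengths(network)
    if not lengths:
        raise ValueError("no finite-distance pairs")
    return float(np.mean(lengths))


def network_diameter(network: WeightedNetwork) -> float:
    """Greatest finite shortest-path distance between any pair of nodes."""
    lengths = _shortest_path_lengths(network)
    if not lengths:
        raise ValueError("no finite-distance pairs")
    return float(np.max(lengths))


def partition_proportions(
    network: WeightedNetwork, communities: list[set[str]]
) -> CommunityPartition:
    """Module-level proportion matrix c for a given node partition."""
    module_of = {}
    for mod_id, comm in enumerate(communities):
        for node in comm:
            module_of[node] = mod_id
    n_mod = len(communities)
    mask = network.edge_mask()
    n = network.n_roi
    c = np.zeros((n_mod, n_mod))
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if not mask[i, j]:
                continue
            w = network.weights[i, j]
            total += w
            a = module_of[network.roi_labels[i]]
            b = module_of[network.roi_labels[j]]
            if a == b:
                c[a, a] += w
            else:
                c[a, b] += w / 2.0
                c[b, a] += w / 2.0
    if total == 0.0:
        raise ValueError("total edge weight is zero")
    return CommunityPartition(assignment=module_of, c=c / total)


def modularity_from_partition(
    network: WeightedNetwork, communities: list[set[str]]
) -> tuple[float, CommunityPartition]:
    part = partition_proportions(network, communities)
    c = part.c
    mod = float(np.sum(np.diag(c) - c.sum(axis=1) ** 2))
    return mod, part


def modularity(
    network: WeightedNetwork, seed: int = 0
) -> tuple[float, CommunityPartition]:
    """Modularity of the best partition found by agglomerative heuristics.

    Runs seeded Louvain and greedy (CNM) modularity maximization and scores
    both partitions — plus the trivial single-module partition — with the
    proportion formula, returning the best.  Deterministic for a fixed seed.
    """
    g = to_networkx(network)
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    candidates: list[list[set[str]]] = [[set(g.nodes)]]
    candidates.append(
        [set(c) for c in nx.community.louvain_communities(g, weight="weight", seed=seed)]
    )
    candidates.append(
        [set(c) for c in nx.community.greedy_modularity_communities(g, weight="weight")]
    )
    best: tuple[float, CommunityPartition] | None = None
    for communities in candidates:
        mod, part = modularity_from_partition(network, communities)
        if best is None or mod > best[0]:
            best = (mod, part)
    assert best is not None
    return best
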