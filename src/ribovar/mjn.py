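"""Minimum-spanning and median-joining haplotype networks.

The minimum spanning network (MSN) is the union of all minimum spanning
trees of the haplotype set under the absolute-difference distance: weights
are swept in increasing order and, at each weight class, every edge of that
weight (relaxed by the tolerance epsilon) joining two components that were
distinct when the class was entered is admitted.

The median-joining network (MJN) iterates: build the epsilon-relaxed
spanning network over the current node set; for every triplet of mutually
well-connected nodes compute the sitewise median (consensus) vector;
among candidate medians not yet in the network, add the one that most
reduces the total connection cost (the minimum-spanning-tree cost of the
node set, the lambda criterion); repeat until no candidate improves, then
prune superfluous median vectors. With epsilon = 0 the network retains only
most-parsimonious connections.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from ribovar.popgen import HaplotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """MJN construction parameters.

    epsilon = 0 (default) is the stringent parsimony setting; larger values
    admit proportionally costlier feasible links at every sweep threshold.
    """

    epsilon: int = 0
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be a nonnegative integer")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class MJNGraph:
    """Haplotype network: sampled + median-vector nodes, weighted edges.

    Nodes are keyed by their residue string over usable columns (unique by
    construction). Sampled nodes carry frequency, member ids and optional
    population composition; ``median_vector`` nodes are inferred
    intermediates with frequency 0.
    """

    graph: nx.Graph
    epsilon: int
    lambda_cost: float  # final total connection cost (MST cost of node set)

    @property
    def n_medians(self) -> int:
        return sum(
            1 for _, d in self.graph.nodes(data=True) if d["kind"] == "median_vector"
        )

    def median_vectors(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "median_vector"
        )

    def total_cost(self) -> float:
        """Sum of edge weights of the network."""
        return float(sum(w for _, _, w in self.graph.edges(data="weight")))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _distance_matrix(nodes: Sequence[str]) -> np.ndarray:
    mats = np.frombuffer("".join(nodes).encode("ascii"), dtype=np.uint8).reshape(
        len(nodes), -1
    )
    return (mats[:, None, :] != mats[None, :, :]).sum(axis=2)


def _mst_cost(nodes: Sequence[str]) -> float:
    if len(nodes) < 2:
        return 0.0
    d = _distance_matrix(nodes)
    return float(minimum_spanning_tree(d).sum())


def _spanning_edges(nodes: Sequence[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Union-of-MSTs edge set with epsilon relaxation (indices into nodes)."""
    n = len(nodes)
    if n < 2:
        return []
    d = _distance_matrix(nodes)
    pairs = [(int(d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    weights = sorted({w for w, _, _ in pairs})
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: set[tuple[int, int, int]] = set()
    for w in weights:
        comp = [find(i) for i in range(n)]
        if len(set(comp)) == 1:
            break
        batch = [
            (wt, i, j)
            for wt, i, j in pairs
            if w <= wt <= w + epsilon and comp[i] != comp[j]
        ]
        for wt, i, j in batch:
            edges.add((wt, i, j))
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return sorted(edges)


def _build_graph(
    nodes: Sequence[str],
    sampled: Mapping[str, dict],
    epsilon: int,
) -> nx.Graph:
    g = nx.Graph()
    median_counter = 0
    for residues in nodes:
        if residues in sampled:
            g.add_node(residues, kind="sampled", **sampled[residues])
        else:
            median_counter += 1
            g.add_node(
                residues,
                kind="median_vector",
                label=f"mv{median_counter}",
                frequency=0,
                members="",
                populations="",
            )
    for w, i, j in _spanning_edges(nodes, epsilon):
        g.add_edge(nodes[i], nodes[j], weight=int(w))
    return g


def _sampled_attrs(
    table: HaplotypeTable, populations: Mapping[str, str] | None
) -> dict[str, dict]:
    attrs = {}
    for k, hap in enumerate(table.haplotypes):
        comp = ""
        if populations is not None:
            counts: dict[str, int] = {}
            for sid in hap.member_ids:
                pop = populations[sid]
                counts[pop] = counts.get(pop, 0) + 1
            comp = ",".join(f"{p}:{c}" for p, c in sorted(counts.items()))
        attrs[hap.residues] = {
            "label": f"H{k + 1}",
            "frequency": hap.frequency,
            "members": ",".join(hap.member_ids),
            "populations": comp,
        }
    return attrs


def minimum_spanning_network(
    table: HaplotypeTable,
    epsilon: int = 0,
    populations: Mapping[str, str] | None = None,
) -> MJNGraph:
    """Union-of-all-MSTs network over the sampled haplotypes (no medians)."""
    sampled = _sampled_attrs(table, populations)
    nodes = sorted(sampled)  # deterministic node order
    g = _build_graph(nodes, sampled, epsilon)
    return MJNGraph(graph=g, epsilon=epsilon, lambda_cost=_mst_cost(nodes))


def _triplet_median(u: str, v: str, w: str) -> str:
    """Sitewise majority consensus of three haplotypes.

    Where all three states differ, the state of the overall-closest member
    (smallest summed distance to the other two, ties broken by lexicographic
    order) is used.
    """
    trio = [u, v, w]
    dist_sum = {
        x: sum(_hamming(x, y) for y in trio if y is not x) for x in trio
    }
    closest = min(trio, key=lambda x: (dist_sum[x], x))
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(closest[len(out)])
    return "".join(out)


def median_joining_network(
    table: HaplotypeTable,
    config: NetworkConfig = NetworkConfig(),
    populations: Mapping[str, str] | None = None,
) -> MJNGraph:
    """Median-joining network over the sampled haplotypes.

    Candidate median vectors come from triplets with at least two mutual
    links in the current spanning network; one cost-reducing candidate (the
    best, deterministic under ties) is added per iteration until the total
    connection cost can no longer be reduced. Superfluous medians (degree
    <= 2 whose removal leaves the minimal connection cost unchanged) are
    pruned afterwards.
    """
    sampled = _sampled_attrs(table, populations)
    nodes = sorted(sampled)
    for _ in range(config.max_iterations):
        cost = _mst_cost(nodes)
        net = _build_graph(nodes, sampled, config.epsilon)
        candidates = set()
        for u, v, w in _linked_triplets(net):
            m = _triplet_median(u, v, w)
            if m not in net:
                candidates.add(m)
        best: tuple[float, str] | None = None
        for m in sorted(candidates):
            new_cost = _mst_cost(nodes + [m])
            if new_cost < cost - 1e-9:
                if best is None or (new_cost, m) < best:
                    best = (new_cost, m)
        if best is None:
            break
        nodes = sorted(nodes + [best[1]])
    else:
        raise RuntimeError(
            f"median-joining did not converge within {config.max_iterations} "
            f"iterations ({len(nodes) - len(sampled)} medians added so far)"
        )
    nodes = _prune_medians(nodes, set(sampled), config.epsilon)
    g = _build_graph(nodes, sampled, config.epsilon)
    return MJNGraph(graph=g, epsilon=config.epsilon, lambda_cost=_mst_cost(nodes))


def _linked_triplets(net: nx.Graph):
    """Triplets of nodes with >= 2 mutual links, in deterministic order."""
    triplets = []
    for u, v, w in itertools.combinations(sorted(net.nodes), 3):
        links = int(net.has_edge(u, v)) + int(net.has_edge(u, w)) + int(
            net.has_edge(v, w)
        )
        if links >= 2:
            dmax = max(_hamming(u, v), _hamming(u, w), _hamming(v, w))
            triplets.append((dmax, u, v, w))
    return [(u, v, w) for _, u, v, w in sorted(triplets)]


def _prune_medians(
    nodes: list[str], sampled: set[str], epsilon: int
) -> list[str]:
    """Drop median vectors that no longer pay for themselves.

    A median of degree <= 2 in the current network is removed when the
    minimal connection cost (MST cost) of the remaining nodes does not
    increase. Repeats to a fixed point.
    """
    nodes = sorted(nodes)
    changed = True
    while changed:
        changed = False
        net = _build_graph(nodes, {s: {} for s in sampled if s in nodes}, epsilon)
        cost = _mst_cost(nodes)
        for m in sorted(n for n in nodes if n not in sampled):
            if net.degree(m) <= 2:
                rest = [n for n in nodes if n != m]
                if _mst_cost(rest) <= cost + 1e-9:
                    nodes = rest
                    changed = True
                    break
    return nodes


def export_graph(graph: MJNGraph, path: str | Path) -> None:
    """Write the network as GraphML with node/edge attributes.

    Node attributes: kind, label, frequency, members, populations; edge
    attribute: weight (mutational differences). Output is deterministic for
    identical input. Raises ``ValueError`` on an empty graph.
    """
    if graph.graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    g = nx.Graph()
    g.graph["epsilon"] = graph.epsilon
    g.graph["lambda_cost"] = graph.lambda_cost
    for n in sorted(graph.graph.nodes):
        g.add_node(n, **graph.graph.nodes[n])
    for u, v in sorted(map(lambda e: tuple(sorted(e)), graph.graph.edges)):
        g.add_edge(u, v, weight=int(graph.graph.edges[u, v]["weight"]))
    nx.write_graphml(g, str(path))


def node_table(graph: MJNGraph):
    """Node attribute table (haplotype, kind, frequency, populations)."""
    import pandas as pd

    rows = []
    for n in sorted(graph.graph.nodes):
        d = graph.graph.nodes[n]
        rows.append(
            {
                "haplotype": d.get("label", n),
                "residues": n,
                "kind": d["kind"],
                "frequency": d.get("frequency", 0),
                "populations": d.get("populations", ""),
            }
        )
    return pd.DataFrame(rows)
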