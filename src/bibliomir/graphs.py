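"""Collaboration and keyword co-occurrence networks with community detection.

Graphs are undirected with node occurrence weights (how many articles
carry the country/keyword) and edge co-occurrence weights. Edge weights
can be association-strength normalised — ``s_ij = 2m * c_ij / (w_i * w_j)``
with ``m`` the total link weight — which compares observed co-occurrence
with the expectation under independence, the normalisation used by
science-mapping tools for keyword maps.

Two community detectors are provided: Walktrap (short-random-walk
agglomeration, via igraph's Pons-Latapy implementation, run per connected
component) and a resolution-parameterised modularity variant optimised by
seeded multi-level local moving, with VOS-style small-cluster merging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import igraph as ig
import networkx as nx
import numpy as np

from .corpus import Corpus
from .geo import load_country_aliases, record_author_countries
from .keywords import Thesaurus, record_keywords

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class WeightedGraph:
    """Node-weighted, edge-weighted undirected graph without self-loops."""

    nodes: dict[str, float] = field(default_factory=dict)
    edges: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != _pair(a, b):
                raise ValueError(f"edge {(a, b)!r} not stored in sorted order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)!r} references a missing node")
            if w < 0:
                raise ValueError("negative edge weight")

    @property
    def total_link_weight(self) -> float:
        return sum(self.edges.values())

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            return
        key = _pair(a, b)
        self.edges[key] = self.edges.get(key, 0.0) + weight

    def neighbors(self, node: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for (a, b), w in self.edges.items():
            if a == node:
                out[b] = w
            elif b == node:
                out[a] = w
        return out

    def degree(self, node: str) -> int:
        return sum(1 for (a, b) in self.edges if node in (a, b))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, w in self.nodes.items():
            g.add_node(node, weight=w)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def to_igraph(self) -> ig.Graph:
        names = sorted(self.nodes)
        index = {n: i for i, n in enumerate(names)}
        g = ig.Graph(
            n=len(names),
            edges=[(index[a], index[b]) for a, b in self.edges],
        )
        g.vs["name"] = names
        g.vs["weight"] = [self.nodes[n] for n in names]
        g.es["weight"] = [self.edges[e] for e in self.edges]
        return g


@dataclass
class Partition:
    """Cluster assignment of every graph node.

    Labels are dense integers ordered by decreasing cluster size. Labels
    in ``residual`` mark clusters that stayed below ``min_cluster_size``
    and had no connection to merge along.
    """

    assignment: dict[str, int]
    min_cluster_size: int = 1
    residual: set[int] = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, label: int) -> set[str]:
        return {n for n, lab in self.assignment.items() if lab == label}


# ---------------------------------------------------------------------------
# network construction

def collaboration_network(
    corpus: Corpus, country_table: dict[str, str] | None = None
) -> WeightedGraph:
    """Country collaboration graph (full counting).

    Node weight: articles with at least one author from the country.
    Edge weight: articles with at least one author from each endpoint.
    """
    if country_table is None:
        country_table = load_country_aliases()
    graph = WeightedGraph()
    for rec in corpus:
        countries = sorted(set(record_author_countries(rec, country_table)))
        for c in countries:
            graph.nodes[c] = graph.nodes.get(c, 0.0) + 1.0
        for i, a in enumerate(countries):
            for b in countries[i + 1 :]:
                graph.add_edge(a, b, 1.0)
    return graph


def cooccurrence_network(
    corpus: Corpus,
    thesaurus: Thesaurus | None = None,
    min_occurrence: int = 5,
    counting: Literal["full", "fractional"] = "fractional",
) -> WeightedGraph:
    """Keyword co-occurrence graph over normalised author keywords.

    Keywords below ``min_occurrence`` articles are dropped before pairing.
    Full counting adds 1 per kept-keyword pair per article; fractional
    counting adds ``1/(k-1)`` per pair in an article with k kept keywords,
    so each keyword distributes exactly unit weight per article.
    """
    per_record = [record_keywords(rec, thesaurus) for rec in corpus]
    occurrence: dict[str, int] = {}
    for kws in per_record:
        for kw in kws:
            occurrence[kw] = occurrence.get(kw, 0) + 1
    kept = {kw for kw, n in occurrence.items() if n >= min_occurrence}
    graph = WeightedGraph(nodes={kw: float(occurrence[kw]) for kw in kept})
    for kws in per_record:
        in_article = sorted(kws & kept)
        k = len(in_article)
        if k < 2:
            continue
        increment = 1.0 if counting == "full" else 1.0 / (k - 1)
        for i, a in enumerate(in_article):
            for b in in_article[i + 1 :]:
                graph.add_edge(a, b, increment)
    return graph


def normalize_association(graph: WeightedGraph) -> WeightedGraph:
    """Association-strength normalisation ``s_ij = 2m * c_ij / (w_i * w_j)``.

    Node weights are preserved; edge support is preserved (s > 0 iff c > 0).
    """
    m = graph.total_link_weight
    edges: dict[Pair, float] = {}
    for (a, b), c in graph.edges.items():
        wa, wb = graph.nodes[a], graph.nodes[b]
        if wa <= 0 or wb <= 0:
            raise ValueError(f"zero node weight on edge {(a, b)!r}")
        edges[(a, b)] = 2.0 * m * c / (wa * wb)
    return WeightedGraph(nodes=dict(graph.nodes), edges=edges)


# ---------------------------------------------------------------------------
# community detection

def walktrap_communities(graph: WeightedGraph, walk_length: int = 4) -> Partition:
    """Pons-Latapy random-walk agglomerative clustering, cut at max modularity.

    Connected components are clustered independently, so disconnected
    graphs (and isolated nodes) are handled; the result is deterministic
    for a given graph and walk length.
    """
    g = graph.to_igraph()
    assignment: dict[str, int] = {}
    next_label = 0
    for comp in g.connected_components():
        sub = g.subgraph(comp)
        if sub.vcount() == 1:
            assignment[sub.vs[0]["name"]] = next_label
            next_label += 1
            continue
        dendrogram = sub.community_walktrap(weights="weight", steps=walk_length)
        clustering = dendrogram.as_clustering()
        for local_label, members in enumerate(clustering):
            for v in members:
                assignment[sub.vs[v]["name"]] = next_label + local_label
        next_label += len(clustering)
    return Partition(assignment=_relabel_by_size(assignment))


def _relabel_by_size(assignment: dict[str, int]) -> dict[str, int]:
    sizes: dict[int, int] = {}
    for lab in assignment.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    order = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    remap = {lab: i for i, lab in enumerate(order)}
    return {n: remap[lab] for n, lab in assignment.items()}


def _quality(
    assignment: dict[str, int],
    graph: WeightedGraph,
    gamma: float,
    m: float,
) -> float:
    q = sum(w for (a, b), w in graph.edges.items() if assignment[a] == assignment[b])
    cluster_w: dict[int, float] = {}
    cluster_sq: dict[int, float] = {}
    for node, lab in assignment.items():
        w = graph.nodes[node]
        cluster_w[lab] = cluster_w.get(lab, 0.0) + w
        cluster_sq[lab] = cluster_sq.get(lab, 0.0) + w * w
    expected = sum((W * W - cluster_sq[lab]) / 2.0 for lab, W in cluster_w.items())
    return q - gamma * expected / (2.0 * m)


def _local_moving(
    names: list[str],
    weights: dict[str, float],
    adjacency: dict[str, dict[str, float]],
    gamma_over_2m: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """One Louvain-style level: greedy node moves until no gain."""
    cluster = {n: i for i, n in enumerate(names)}
    cluster_weight = {i: weights[n] for i, n in enumerate(names)}
    improved = True
    while improved:
        improved = False
        for idx in rng.permutation(len(names)):
            node = names[idx]
            w = weights[node]
            old = cluster[node]
            links: dict[int, float] = {}
            for nbr, s in adjacency[node].items():
                lab = cluster[nbr]
                links[lab] = links.get(lab, 0.0) + s
            # gain of staying computed against leaving the (old minus node) cluster
            base = links.get(old, 0.0) - gamma_over_2m * w * (cluster_weight[old] - w)
            best_lab, best_gain = old, 0.0
            for lab, s_to in links.items():
                if lab == old:
                    continue
                gain = (s_to - gamma_over_2m * w * cluster_weight[lab]) - base
                if gain > best_gain + 1e-12:
                    best_lab, best_gain = lab, gain
            if best_lab != old:
                cluster[node] = best_lab
                cluster_weight[old] -= w
                cluster_weight[best_lab] += w
                improved = True
    return cluster


def _multilevel(
    graph: WeightedGraph, gamma: float, m: float, rng: np.random.Generator
) -> dict[str, int]:
    names = sorted(graph.nodes)
    weights = dict(graph.nodes)
    edges = dict(graph.edges)
    mapping = {n: n for n in names}  # original node -> current super-node
    gamma_over_2m = gamma / (2.0 * m) if m > 0 else 0.0
    while True:
        adjacency: dict[str, dict[str, float]] = {n: {} for n in names}
        for (a, b), s in edges.items():
            adjacency[a][b] = adjacency[a].get(b, 0.0) + s
            adjacency[b][a] = adjacency[b].get(a, 0.0) + s
        cluster = _local_moving(names, weights, adjacency, gamma_over_2m, rng)
        labels = sorted(set(cluster.values()))
        if len(labels) == len(names):
            break
        # aggregate clusters into super-nodes and repeat one level up
        label_name = {lab: f"c{idx}" for idx, lab in enumerate(labels)}
        new_weights: dict[str, float] = {}
        for n, lab in cluster.items():
            sn = label_name[lab]
            new_weights[sn] = new_weights.get(sn, 0.0) + weights[n]
        new_edges: dict[Pair, float] = {}
        for (a, b), s in edges.items():
            sa, sb = label_name[cluster[a]], label_name[cluster[b]]
            if sa == sb:
                continue
            key = _pair(sa, sb)
            new_edges[key] = new_edges.get(key, 0.0) + s
        mapping = {orig: label_name[cluster[sn]] for orig, sn in mapping.items()}
        names = sorted(new_weights)
        weights, edges = new_weights, new_edges
    final_labels = {sn: i for i, sn in enumerate(names)}
    return {orig: final_labels[sn] for orig, sn in mapping.items()}


def resolution_clustering(
    graph: WeightedGraph,
    resolution: float = 0.5,
    min_cluster_size: int = 10,
    n_restarts: int = 10,
    seed: int = 20240925,
) -> Partition:
    """Resolution-parameterised clustering in the VOS style.

    Maximises ``sum_{i<j same cluster} (s_ij - gamma * w_i * w_j / (2m))``
    — observed minus resolution-scaled configuration-model expectation on
    node occurrence weights — by multi-level local moving with seeded
    random restarts, keeping the best-quality restart. Clusters smaller
    than ``min_cluster_size`` are then merged into the neighbouring
    cluster with the largest connecting weight; unconnected small clusters
    are flagged residual instead.
    """
    if not graph.nodes:
        return Partition(assignment={}, min_cluster_size=min_cluster_size)
    m = graph.total_link_weight
    if m == 0:
        assignment = {n: i for i, n in enumerate(sorted(graph.nodes))}
        return Partition(_relabel_by_size(assignment), min_cluster_size)
    master = np.random.default_rng(seed)
    best: dict[str, int] | None = None
    best_q = -np.inf
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(0, 2**31))
        assignment = _multilevel(graph, resolution, m, rng)
        q = _quality(assignment, graph, resolution, m)
        if q > best_q:
            best, best_q = assignment, q
    assert best is not None
    merged, residual = _merge_small_clusters(best, graph, min_cluster_size)
    sizes: dict[int, int] = {}
    for lab in merged.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    remap = {lab: i for i, lab in enumerate(sorted(sizes, key=lambda l: (-sizes[l], l)))}
    assignment = {n: remap[lab] for n, lab in merged.items()}
    return Partition(assignment, min_cluster_size, {remap[lab] for lab in residual})


def _merge_small_clusters(
    assignment: dict[str, int], graph: WeightedGraph, min_cluster_size: int
) -> tuple[dict[str, int], set[int]]:
    assignment = dict(assignment)
    residual: set[int] = set()
    while True:
        sizes: dict[int, int] = {}
        for lab in assignment.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        small = sorted(
            (lab for lab, n in sizes.items() if n < min_cluster_size and lab not in residual),
            key=lambda lab: (sizes[lab], lab),
        )
        if not small or len(sizes) <= 1:
            residual.update(small)  # nothing left to merge into: flag, don't hide
            break
        lab = small[0]
        connect: dict[int, float] = {}
        for (a, b), w in graph.edges.items():
            la, lb = assignment[a], assignment[b]
            if la == lab and lb != lab:
                connect[lb] = connect.get(lb, 0.0) + w
            elif lb == lab and la != lab:
                connect[la] = connect.get(la, 0.0) + w
        if not connect:
            residual.add(lab)
            continue
        target = max(sorted(connect), key=lambda l: connect[l])
        for node, l in assignment.items():
            if l == lab:
                assignment[node] = target
    return assignment, residual


# ---------------------------------------------------------------------------
# pruning and export

def prune_network(
    graph: WeightedGraph, max_nodes: int = 30, min_edges_per_node: int = 1
) -> WeightedGraph:
    """Reporting prune: top nodes by weight, then drop under-connected nodes.

    Keeps the ``max_nodes`` heaviest nodes (ties lexicographic), drops
    edges to removed nodes, then iteratively removes nodes whose degree
    falls below ``min_edges_per_node`` (isolates included).
    """
    order = sorted(graph.nodes, key=lambda n: (-graph.nodes[n], n))
    kept = set(order[:max_nodes])
    edges = {e: w for e, w in graph.edges.items() if e[0] in kept and e[1] in kept}
    while True:
        degree: dict[str, int] = {n: 0 for n in kept}
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1
        dropping = {n for n in kept if degree[n] < min_edges_per_node}
        if not dropping:
            break
        kept -= dropping
        edges = {e: w for e, w in edges.items() if e[0] in kept and e[1] in kept}
    return WeightedGraph(nodes={n: graph.nodes[n] for n in sorted(kept)}, edges=edges)


def write_graphml(graph: WeightedGraph, path: str | Path, partition: Partition | None = None) -> None:
    g = graph.to_networkx()
    if partition is not None:
        nx.set_node_attributes(g, partition.assignment, "cluster")
    nx.write_graphml(g, str(path))


def node_link_json(graph: WeightedGraph, partition: Partition | None = None) -> str:
    payload = {
        "nodes": [
            {
                "id": n,
                "weight": w,
                **({"cluster": partition.assignment[n]} if partition else {}),
            }
            for n, w in sorted(graph.nodes.items())
        ],
        "links": [
            {"source": a, "target": b, "weight": w}
            for (a, b), w in sorted(graph.edges.items())
        ],
    }
    return json.dumps(payload, indent=1)
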