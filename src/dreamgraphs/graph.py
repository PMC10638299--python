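"""Directed word-adjacency multigraphs and their structural attributes.

Every report becomes one graph: each distinct content lemma is a node and
each consecutive lemma pair contributes one directed edge, repeats included.
The graph is therefore a multigraph whose edge multiplicities encode lemma
recurrence — the quantity the whole analysis is about.

Fourteen attributes are computed per graph:

recurrence    PE (parallel edges beyond the first per ordered pair),
              L1/L2/L3 (loops through one, two, three nodes, from powers of
              the multiplicity adjacency matrix)
connectivity  LSC (largest strongly connected component size), ATD = 2E/N,
              density = E/(N(N−1)), mean average-neighbor degree
global        diameter and ASP over reachable ordered pairs, mean clustering
              coefficient, mean betweenness centrality

Conventions for degenerate and directed/undirected cases are fixed here and
documented in the methods note: shortest paths, strong connectivity and
betweenness use the directed simple projection (multiplicities and self-loops
dropped); clustering and neighbor degree use the undirected simple
projection; path statistics average over reachable ordered pairs only and
are 0 when none exist, so disconnected or single-node graphs never produce
infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .annotation import LemmaSequence


class EmptySequenceError(ValueError):
    """Signals a report whose content-lemma sequence is empty (skip it)."""

    def __init__(self, report_id: str):
        super().__init__(f"report {report_id!r} has no content lemmas; skipped")
        self.report_id = report_id


@dataclass(frozen=True)
class SpeechGraph:
    """Word-adjacency multigraph: nodes are lemmas, edges ordered pairs."""

    report_id: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) endpoint not in nodes")


@dataclass(frozen=True)
class GraphAttributes:
    N: int
    E: int
    PE: int
    L1: int
    L2: int
    L3: int
    LSC: int
    ATD: float
    density: float
    diameter: float
    ASP: float
    CC: float
    mean_betweenness: float
    avg_neighbor_degree: float

    def as_dict(self) -> dict:
        return asdict(self)


def build_graph(seq: LemmaSequence) -> SpeechGraph:
    """Chain consecutive content lemmas into the directed multigraph."""
    if not seq.lemmas:
        raise EmptySequenceError(seq.report_id)
    edges = tuple(zip(seq.lemmas[:-1], seq.lemmas[1:]))
    return SpeechGraph(report_id=seq.report_id,
                       nodes=frozenset(seq.lemmas), edges=edges)


def _adjacency(g: SpeechGraph) -> tuple[np.ndarray, list[str]]:
    """Multiplicity adjacency matrix with a sorted, stable node order."""
    order = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(order)}
    A = np.zeros((len(order), len(order)), dtype=np.int64)
    for u, v in g.edges:
        A[idx[u], idx[v]] += 1
    return A, order


def _simple_digraph(g: SpeechGraph) -> nx.DiGraph:
    """Directed simple projection: multiplicities collapsed, self-loops kept
    out (they never affect reachability, paths or betweenness)."""
    G = nx.DiGraph()
    G.add_nodes_from(g.nodes)
    G.add_edges_from((u, v) for u, v in set(g.edges) if u != v)
    return G


def _simple_graph(g: SpeechGraph) -> nx.Graph:
    """Undirected simple projection, self-loops dropped."""
    G = nx.Graph()
    G.add_nodes_from(g.nodes)
    G.add_edges_from((u, v) for u, v in set(g.edges) if u != v)
    return G


def cycle_counts(g: SpeechGraph) -> tuple[int, int, int]:
    """Loop counts from powers of the multiplicity adjacency matrix.

    L1 = tr(A); L2 = ⌊tr(A²)/2⌋; L3 = ⌊tr(A³)/3⌋. The traces are taken on
    the full multiplicity matrix, so on graphs mixing self-loops with
    reciprocal edges L2/L3 count closed walks rather than pure simple
    cycles; on self-loop-free graphs they equal the exhaustive cycle
    enumeration exactly (a tested invariant).
    """
    A, _ = _adjacency(g)
    L1 = int(np.trace(A))
    A2 = A @ A
    L2 = int(np.trace(A2)) // 2
    L3 = int(np.trace(A2 @ A)) // 3
    return L1, L2, L3


def parallel_edge_count(g: SpeechGraph) -> int:
    """Repeated directed adjacencies beyond the first per ordered pair."""
    A, _ = _adjacency(g)
    return int(np.maximum(A - 1, 0).sum())


def lsc_size(g: SpeechGraph) -> int:
    """Node count of the largest strongly connected component."""
    G = _simple_digraph(g)
    return max(len(c) for c in nx.strongly_connected_components(G))


def path_stats(g: SpeechGraph) -> tuple[float, float]:
    """(diameter, ASP) over reachable ordered pairs u ≠ v; (0, 0) if none."""
    G = _simple_digraph(g)
    lengths = [d for u, dists in nx.all_pairs_shortest_path_length(G)
               for v, d in dists.items() if u != v]
    if not lengths:
        return 0.0, 0.0
    return float(max(lengths)), float(np.mean(lengths))


def mean_clustering(g: SpeechGraph) -> float:
    """Mean local clustering on the undirected simple projection; nodes with
    degree < 2 contribute 0."""
    G = _simple_graph(g)
    if G.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(G, count_zeros=True))


def mean_betweenness(g: SpeechGraph) -> float:
    """Mean betweenness centrality on the directed simple projection.

    Pair dependencies are normalized by (N−1)(N−2)/2, so a node lying on
    every shortest path of a directed path graph scores 1; 0 for N < 3.
    """
    n = len(g.nodes)
    if n < 3:
        return 0.0
    G = _simple_digraph(g)
    raw = nx.betweenness_centrality(G, normalized=False)
    scale = (n - 1) * (n - 2) / 2.0
    return float(np.mean([b / scale for b in raw.values()]))


def avg_neighbor_degree_mean(g: SpeechGraph) -> float:
    """Mean over non-isolated nodes of their neighbors' mean degree
    (undirected simple projection); 0 for an edgeless graph."""
    G = _simple_graph(g)
    vals = [float(np.mean([G.degree(w) for w in G[v]]))
            for v in G if G.degree(v) > 0]
    return float(np.mean(vals)) if vals else 0.0


def compute_attributes(g: SpeechGraph) -> GraphAttributes:
    """All fourteen structural attributes of one dream graph."""
    n = len(g.nodes)
    if n == 0:
        raise EmptySequenceError(g.report_id)
    e = len(g.edges)
    L1, L2, L3 = cycle_counts(g)
    diameter, asp = path_stats(g)
    return GraphAttributes(
        N=n,
        E=e,
        PE=parallel_edge_count(g),
        L1=L1, L2=L2, L3=L3,
        LSC=lsc_size(g),
        ATD=2.0 * e / n,
        density=e / (n * (n - 1)) if n >= 2 else 0.0,
        diameter=diameter,
        ASP=asp,
        CC=mean_clustering(g),
        mean_betweenness=mean_betweenness(g),
        avg_neighbor_degree=avg_neighbor_degree_mean(g),
    )


def attributes_from_sequences(seqs, on_skip=None) -> list[dict]:
    """Per-dream attribute rows for a batch of lemma sequences.

    Empty sequences are skipped; ``on_skip(report_id)`` is called for each.
    """
    rows = []
    for seq in seqs:
        try:
            attrs = compute_attributes(build_graph(seq))
        except EmptySequenceError as exc:
            if on_skip is not None:
                on_skip(exc.report_id)
            continue
        row = {"report_id": seq.report_id, "n_raw_tokens": seq.n_raw_tokens}
        row.update(attrs.as_dict())
        rows.append(row)
    return rows


def export_graph(g: SpeechGraph, path, format: str = "graphml") -> None:
    """Write a graph as GraphML (multigraph, labels on nodes) or as a TSV
    edge list with one line per edge occurrence in narrative order."""
    if format == "graphml":
        G = nx.MultiDiGraph()
        for node in sorted(g.nodes):
            G.add_node(node, label=node)
        for i, (u, v) in enumerate(g.edges):
            G.add_edge(u, v, order=i)
        nx.write_graphml(G, path)
    elif format == "edgelist_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for u, v in g.edges:
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown graph export format {format!r}")


def import_graph(path, format: str = "graphml",
                 report_id: str = "") -> SpeechGraph:
    """Read a graph written by :func:`export_graph`, restoring edge order."""
    if format == "graphml":
        G = nx.read_graphml(path, force_multigraph=True)
        edges = sorted(G.edges(keys=True, data=True),
                       key=lambda e: int(e[3].get("order", 0)))
        return SpeechGraph(report_id=report_id,
                           nodes=frozenset(G.nodes),
                           edges=tuple((u, v) for u, v, _k, _d in edges))
    if format == "edgelist_tsv":
        edges = []
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                u, v = line.rstrip("\n").split("\t")
                edges.append((u, v))
        nodes = frozenset(n for e in edges for n in e)
        return SpeechGraph(report_id=report_id, nodes=nodes,
                           edges=tuple(edges))
    raise ValueError(f"unknown graph import format {format!r}")
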