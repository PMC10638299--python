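"""Word-frequency tables and sentence-adjacency co-occurrence networks.

Co-occurrence here means *immediate adjacency within a sentence*: for every
sentence, each adjacent pair of retained words adds one to the undirected
edge between them. Adjacency never crosses a sentence boundary and
self-pairs contribute nothing. The network is restricted to the top-k most
frequent words; ranking uses descending count with lexicographic
tie-breaking.

By default only content words (NOUN/VERB/ADJ) are retained, but the filter
can be switched off — the most central words in real dream corpora include
auxiliaries like *haber* and *ser*, which the content filter would remove.
Centrality is weighted degree divided by total edge weight; betweenness is
available as an alternative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .annotation import AnnotatedToken, CONTENT_POS


@dataclass(frozen=True)
class CooccurrenceNetwork:
    nodes: tuple[tuple[str, int], ...]          # (word, frequency), ranked
    edges: tuple[tuple[str, str, int], ...]     # (a, b, count), a < b
    centrality: dict


def _retained(tokens, unit: str, content_only: bool):
    for t in tokens:
        if content_only and t.pos not in CONTENT_POS:
            continue
        yield (t.lemma if unit == "lemma" else t.surface.lower(),
               t.sentence_index)


def term_frequencies(reports: dict[str, list[AnnotatedToken]],
                     unit: str = "lemma",
                     content_only: bool = True) -> list[tuple[str, int]]:
    """Ranked (word, count) list over a set of annotated reports."""
    if not reports:
        raise ValueError("empty corpus subset")
    if unit not in ("lemma", "surface"):
        raise ValueError(f"unknown unit {unit!r}")
    counts: Counter = Counter()
    for tokens in reports.values():
        counts.update(w for w, _s in _retained(tokens, unit, content_only))
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def cooccurrence_edges(reports: dict[str, list[AnnotatedToken]],
                       top_k: int, unit: str = "lemma",
                       content_only: bool = True) -> CooccurrenceNetwork:
    """Build the sentence-adjacency network over the top-k frequent words."""
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    freqs = term_frequencies(reports, unit=unit, content_only=content_only)
    top = freqs[:top_k]
    keep = {w for w, _c in top}
    edge_counts: Counter = Counter()
    for tokens in reports.values():
        # split the retained stream by sentence, then count adjacent pairs
        sentences: dict[int, list[str]] = {}
        for w, s in _retained(tokens, unit, content_only):
            sentences.setdefault(s, []).append(w)
        for words in sentences.values():
            for a, b in zip(words[:-1], words[1:]):
                if a == b or a not in keep or b not in keep:
                    continue
                edge_counts[tuple(sorted((a, b)))] += 1
    edges = tuple(sorted(((a, b, c) for (a, b), c in edge_counts.items())))
    total = sum(c for _a, _b, c in edges)
    wdeg: Counter = Counter()
    for a, b, c in edges:
        wdeg[a] += c
        wdeg[b] += c
    centrality = {w: (wdeg[w] / total if total else 0.0) for w, _c in top}
    return CooccurrenceNetwork(nodes=tuple(top), edges=edges,
                               centrality=centrality)


def central_words(net: CooccurrenceNetwork, top_n: int,
                  metric: str = "weighted_degree") -> list[tuple[str, float]]:
    """Top-n words by centrality (weighted degree share, or betweenness)."""
    if not net.nodes:
        raise ValueError("empty network")
    if metric == "weighted_degree":
        scores = net.centrality
    elif metric == "betweenness":
        G = to_networkx(net)
        scores = nx.betweenness_centrality(G, weight=None)
    else:
        raise ValueError(f"unknown centrality metric {metric!r}")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def to_networkx(net: CooccurrenceNetwork) -> nx.Graph:
    G = nx.Graph()
    for w, c in net.nodes:
        G.add_node(w, frequency=c)
    for a, b, c in net.edges:
        G.add_edge(a, b, weight=c)
    return G


def export_network(net: CooccurrenceNetwork, graphml_path=None,
                   nodes_csv=None, edges_csv=None) -> None:
    """Write the network as GraphML and/or node+edge CSV tables."""
    if graphml_path is not None:
        nx.write_graphml(to_networkx(net), graphml_path)
    if nodes_csv is not None:
        with open(nodes_csv, "w", encoding="utf-8") as fh:
            fh.write("word,frequency,centrality\n")
            for w, c in net.nodes:
                fh.write(f"{w},{c},{net.centrality[w]!r}\n")
    if edges_csv is not None:
        with open(edges_csv, "w", encoding="utf-8") as fh:
            fh.write("word_a,word_b,count\n")
            for a, b, c in net.edges:
                fh.write(f"{a},{b},{c}\n")
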