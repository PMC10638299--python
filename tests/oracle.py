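"""Brute-force reference implementations of every graph attribute.

Deliberately naive and independent of both networkx and the package's own
matrix-trace route: closed walks are counted by enumerating edge-instance
tuples, components by mutual BFS reachability, clustering by triad census,
and betweenness by explicit enumeration of every shortest path. Only usable
for small graphs (N <= ~12, E <= ~40), which is the point.
"""

from collections import Counter


def _nodes_edges(g):
    return sorted(g.nodes), list(g.edges)


def oracle_counts(g):
    """(N, E, PE, L1) by direct bookkeeping."""
    nodes, edges = _nodes_edges(g)
    mult = Counter(edges)
    pe = sum(m - 1 for m in mult.values() if m > 1)
    l1 = sum(1 for u, v in edges if u == v)
    return len(nodes), len(edges), pe, l1


def oracle_closed_walks(g, k):
    """Closed walks of length k counted over ordered edge-instance tuples
    (with repetition) — equals trace(A^k) on the multiplicity matrix."""
    _, edges = _nodes_edges(g)
    by_tail: dict = {}
    for e in edges:
        by_tail.setdefault(e[0], []).append(e)
    total = 0
    if k == 1:
        return sum(1 for u, v in edges if u == v)
    for e1 in edges:
        for e2 in by_tail.get(e1[1], ()):
            if k == 2:
                if e2[1] == e1[0]:
                    total += 1
            else:
                for e3 in by_tail.get(e2[1], ()):
                    if e3[1] == e1[0]:
                        total += 1
    return total


def oracle_L2_L3(g):
    return oracle_closed_walks(g, 2) // 2, oracle_closed_walks(g, 3) // 3


def oracle_distinct_cycles(g):
    """(#2-cycles, #3-cycles) through distinct nodes, counting every
    combination of parallel edge instances; self-loops never participate."""
    nodes, edges = _nodes_edges(g)
    mult = Counter((u, v) for u, v in edges if u != v)
    c2 = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            c2 += mult[(u, v)] * mult[(v, u)]
    c3 = 0
    for a in nodes:
        for b in nodes:
            for c in nodes:
                if len({a, b, c}) == 3:
                    c3 += mult[(a, b)] * mult[(b, c)] * mult[(c, a)]
    return c2, c3 // 3


def _succ(g, directed=True):
    adj = {n: set() for n in g.nodes}
    for u, v in g.edges:
        if u == v:
            continue
        adj[u].add(v)
        if not directed:
            adj[v].add(u)
    return adj


def _bfs_dist(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_lsc(g):
    adj = _succ(g)
    reach = {s: set(_bfs_dist(adj, s)) for s in adj}
    best = 0
    for s in adj:
        scc = {t for t in reach[s] if s in reach[t]}
        best = max(best, len(scc))
    return best


def oracle_paths(g):
    """(diameter, ASP) over finite ordered pairs u != v."""
    adj = _succ(g)
    lengths = []
    for s in adj:
        for t, d in _bfs_dist(adj, s).items():
            if t != s:
                lengths.append(d)
    if not lengths:
        return 0.0, 0.0
    return float(max(lengths)), sum(lengths) / len(lengths)


def oracle_clustering(g):
    """Mean local clustering by triad census on the undirected projection."""
    adj = _succ(g, directed=False)
    # make symmetric
    for u in list(adj):
        for v in adj[u]:
            adj[v].add(u)
    vals = []
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        nb = sorted(nbrs)
        tri = sum(1 for i, x in enumerate(nb) for y in nb[i + 1:]
                  if y in adj[x])
        vals.append(tri / (k * (k - 1) / 2))
    return sum(vals) / len(vals) if vals else 0.0


def _all_shortest_paths(adj, s, t, d):
    """Every path of length exactly d from s to t, by DFS."""
    out = []

    def walk(path):
        u = path[-1]
        if len(path) - 1 == d:
            if u == t:
                out.append(list(path))
            return
        for v in adj[u]:
            if v not in path:  # shortest paths never revisit
                path.append(v)
                walk(path)
                path.pop()

    walk([s])
    return out


def oracle_betweenness_mean(g):
    """Mean betweenness from explicit shortest-path enumeration, pair
    dependencies divided by (N-1)(N-2)/2."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 3:
        return 0.0
    adj = _succ(g)
    dep = {v: 0.0 for v in nodes}
    for s in nodes:
        dist = _bfs_dist(adj, s)
        for t, d in dist.items():
            if t == s or d == 0:
                continue
            paths = _all_shortest_paths(adj, s, t, d)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                dep[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2
    return sum(b / scale for b in dep.values()) / n


def oracle_avg_neighbor_degree(g):
    adj = _succ(g, directed=False)
    for u in list(adj):
        for v in adj[u]:
            adj[v].add(u)
    vals = []
    for v, nbrs in adj.items():
        if nbrs:
            vals.append(sum(len(adj[w]) for w in nbrs) / len(nbrs))
    return sum(vals) / len(vals) if vals else 0.0


def oracle_attributes(g):
    """All fourteen attributes, assembled purely from the routines above."""
    n, e, pe, l1 = oracle_counts(g)
    l2, l3 = oracle_L2_L3(g)
    diameter, asp = oracle_paths(g)
    return {
        "N": n, "E": e, "PE": pe, "L1": l1, "L2": l2, "L3": l3,
        "LSC": oracle_lsc(g),
        "ATD": 2 * e / n if n else 0.0,
        "density": e / (n * (n - 1)) if n >= 2 else 0.0,
        "diameter": diameter, "ASP": asp,
        "CC": oracle_clustering(g),
        "mean_betweenness": oracle_betweenness_mean(g),
        "avg_neighbor_degree": oracle_avg_neighbor_degree(g),
    }


def random_multigraph(rng, max_n=12, max_e=40):
    """Random directed multigraph (self-loops and repeats allowed)."""
    from dreamgraphs import SpeechGraph

    n = int(rng.integers(1, max_n + 1))
    nodes = [f"w{i}" for i in range(n)]
    e = int(rng.integers(0, max_e + 1))
    edges = tuple((nodes[rng.integers(n)], nodes[rng.integers(n)])
                  for _ in range(e))
    return SpeechGraph(report_id="rand", nodes=frozenset(nodes), edges=edges)
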