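"""Independent brute-force oracles used only by the test suite.

Deliberately different algorithms from the package: exhaustive DFS path
enumeration for routes, Floyd-Warshall for distances, distance-pruned DFS
for shortest-path counting, and a continuous-approximation MLE for the
power-law exponent.
"""

import itertools

import numpy as np


def all_simple_paths_upto(adj, source, target, max_edges):
    """Every simple directed path source->target with <= max_edges edges."""
    paths = []

    def dfs(path):
        u = path[-1]
        if u == target:
            paths.append(tuple(path))
            return
        if len(path) > max_edges:
            return
        for v in sorted(adj.get(u, ())):
            if v not in path:
                dfs(path + [v])

    dfs([source])
    return paths


def brute_force_routes(adj, max_stops=2):
    """(stops, lexicographic-first path, n shortest paths) per reachable pair."""
    out = {}
    for s in sorted(adj):
        for t in sorted(adj):
            if s == t:
                continue
            paths = all_simple_paths_upto(adj, s, t, max_stops + 1)
            if not paths:
                continue
            best_len = min(len(p) for p in paths)
            shortest = sorted(p for p in paths if len(p) == best_len)
            out[(s, t)] = (best_len - 2, shortest[0], len(shortest))
    return out


def floyd_warshall(adj):
    nodes = sorted(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u in adj:
        for v in adj[u]:
            dist[idx[u], idx[v]] = 1.0
    for k, i, j in itertools.product(range(n), repeat=3):
        if dist[i, k] + dist[k, j] < dist[i, j]:
            dist[i, j] = dist[i, k] + dist[k, j]
    return nodes, idx, dist


def brute_force_metrics(adj):
    """Closeness (reachable/mean-distance) and betweenness by enumeration."""
    nodes, idx, dist = floyd_warshall(adj)
    closeness = {}
    for v in nodes:
        ds = [dist[idx[v], idx[u]] for u in nodes
              if u != v and np.isfinite(dist[idx[v], idx[u]])]
        closeness[v] = (len(ds) / sum(ds)) if ds and sum(ds) > 0 else 0.0
    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        d = dist[idx[s], idx[t]]
        if not np.isfinite(d) or d < 2:
            continue
        # distance-pruned DFS enumerates exactly the shortest paths
        paths = []

        def dfs(path):
            u = path[-1]
            if u == t:
                paths.append(tuple(path))
                return
            for v in sorted(adj.get(u, ())):
                if dist[idx[s], idx[v]] == len(path) and \
                        dist[idx[s], idx[v]] + dist[idx[v], idx[t]] == d:
                    dfs(path + [v])

        dfs([s])
        for p in paths:
            for v in p[1:-1]:
                betweenness[v] += 1.0 / len(paths)
    return closeness, betweenness


def power_law_mle(samples, xmin=1):
    """Continuous-approximation discrete power-law MLE (Clauset et al. style)."""
    x = np.asarray(samples, dtype=float)
    x = x[x >= xmin]
    return 1.0 + len(x) / np.sum(np.log(x / (xmin - 0.5)))


def random_digraph(rng, n, p):
    """Random directed graph as an adjacency dict over letter codes."""
    codes = [chr(ord("A") + i) for i in range(n)]
    adj = {c: set() for c in codes}
    for u, v in itertools.permutations(codes, 2):
        if rng.random() < p:
            adj[u].add(v)
    return adj
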