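"""Independent brute-force oracles, written against plain adjacency dicts.

These deliberately avoid the graph library used by the implementation: the
betweenness oracle enumerates every shortest path explicitly via its own
breadth-first distances and depth-first path expansion.
"""

from collections import deque


def adjacency(edges, nodes=()):
    adj = {}
    for n in nodes:
        adj.setdefault(n, set())
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def enumerate_shortest_paths(adj, s, t):
    """All shortest s-t paths as node tuples (empty if unreachable)."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def extend(u, acc):
        if u == t:
            paths.append(tuple(acc))
            return
        for v in adj[u]:
            if dist_t.get(v, -1) == dist_t[u] - 1:
                extend(v, acc + [v])

    extend(s, [s])
    return paths


def brute_betweenness(adj):
    """C_B(v) by explicit enumeration over unordered node pairs."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def naive_pearson(x, y):
    """Textbook Pearson correlation, no library calls."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)
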