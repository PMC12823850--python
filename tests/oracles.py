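"""Independent brute-force graph-metric implementations.

These deliberately avoid networkx and any shared code with the package:
distances come from Floyd-Warshall, triangles from explicit neighbor-pair
loops, and betweenness from exhaustive enumeration of all shortest paths.
They are only feasible on tiny graphs and exist to cross-check the efficient
implementations exactly.
"""

from itertools import combinations

INF = float("inf")


def floyd_warshall(adj):
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def bf_clustering(adj):
    """Undirected clustering coefficient by explicit triangle counting."""
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        t = sum(1 for u, v in combinations(nb, 2) if adj[u][v])
        out.append(2.0 * t / (k * (k - 1)))
    return out


def bf_local_efficiency(adj):
    """Undirected local efficiency: inverse distances inside the
    neighborhood subgraph, averaged over ordered neighbor pairs."""
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        sub = [[adj[u][v] for v in nb] for u in nb]
        d = floyd_warshall(sub)
        total = sum(1.0 / d[a][b] for a in range(k) for b in range(k)
                    if a != b and d[a][b] < INF)
        out.append(total / (k * (k - 1)))
    return out


def bf_closeness(adj, direction="out"):
    """1 / (sum of shortest-path lengths over the reachable set)."""
    n = len(adj)
    if direction == "in":
        adj = [[adj[j][i] for j in range(n)] for i in range(n)]
    d = floyd_warshall(adj)
    out = []
    for i in range(n):
        s = sum(d[i][j] for j in range(n) if j != i and d[i][j] < INF)
        out.append(1.0 / s if s > 0 else 0.0)
    return out


def _all_shortest_paths(adj, s, t, length):
    """Every simple path from s to t of exactly the given length (DFS)."""
    n = len(adj)
    paths = []

    def dfs(node, path):
        hops = len(path) - 1
        if node == t:
            if hops == length:
                paths.append(tuple(path))
            return
        if hops >= length:
            return
        for nxt in range(n):
            if adj[node][nxt] and nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(s, [s])
    return paths


def bf_betweenness(adj, directed=False):
    """Unnormalized betweenness by exhaustive shortest-path enumeration.

    Unordered source-target pairs for undirected graphs, ordered pairs for
    directed graphs (matching the convention under test).
    """
    n = len(adj)
    d = floyd_warshall(adj)
    bw = [0.0] * n
    if directed:
        pairs = [(s, t) for s in range(n) for t in range(n) if s != t]
    else:
        pairs = [(s, t) for s in range(n) for t in range(s + 1, n)]
    for s, t in pairs:
        if d[s][t] == INF:
            continue
        paths = _all_shortest_paths(adj, s, t, int(d[s][t]))
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p)
            bw[i] += through / len(paths)
    return bw


def random_adjacency(rng, n, p, directed=False):
    """Seeded random binary adjacency without self-loops."""
    a = (rng.random((n, n)) < p).astype(int)
    for i in range(n):
        a[i, i] = 0
    if not directed:
        a = ((a + a.T) > 0).astype(int)
    return a
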