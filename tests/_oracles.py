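"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the libraries)
they validate: exact rational arithmetic for the Fisher tail, the literal
step-up definition for Benjamini-Hochberg, and exhaustive shortest-path
enumeration for betweenness.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    total = sum((pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs), Fraction(0))
    return float(min(total, Fraction(1)))


def bh_oracle(p) -> list:
    """Literal step-up definition: q_i = min over j with p_j >= p_i of p_(j)*n/j."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q_sorted = [
        min(min(p[order[j]] * n / (j + 1) for j in range(i, n)), 1.0) for i in range(n)
    ]
    q = [0.0] * n
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q


def _bfs_distances(adj: dict, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _count_shortest_paths(adj: dict, s, t, length: int):
    """Enumerate all simple paths of exactly the shortest length via DFS.

    Returns (number of shortest paths, dict node -> number of those paths
    passing through it as an interior node).
    """
    n_paths = 0
    through: dict = {}

    def dfs(node, depth, path):
        nonlocal n_paths
        if node == t:
            if depth == length:
                n_paths += 1
                for interior in path[1:-1]:
                    through[interior] = through.get(interior, 0) + 1
            return
        if depth >= length:
            return
        for nb in adj[node]:
            if nb not in path:
                dfs(nb, depth + 1, path + [nb])

    dfs(s, 0, [s])
    return n_paths, through


def betweenness_oracle(g) -> dict:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    adj = {u: sorted(g.neighbors(u)) for u in g.nodes}
    bc = {u: 0.0 for u in adj}
    for s, t in combinations(sorted(adj), 2):
        dist = _bfs_distances(adj, s)
        if t not in dist:
            continue
        n_paths, through = _count_shortest_paths(adj, s, t, dist[t])
        for node, k in through.items():
            bc[node] += k / n_paths
    return bc


def hypergeom_upper_tail_oracle(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(overlap >= k) drawing n from a universe of N containing K, exactly."""
    denom = comb(big_n, n)
    total = sum(
        Fraction(comb(big_k, j) * comb(big_n - big_k, n - j), denom)
        for j in range(k, min(big_k, n) + 1)
    )
    return float(total)


def ward_linkage_oracle(dist):
    """Greedy Ward agglomeration via the Lance-Williams recurrence.

    ``dist`` is a full symmetric distance matrix (list of lists). Returns the
    merge list [(height, frozenset_of_leaf_ids), ...] in merge order.
    """
    clusters = {i: frozenset([i]) for i in range(len(dist))}
    d = {
        (i, j): float(dist[i][j])
        for i in range(len(dist))
        for j in range(i + 1, len(dist))
    }
    sizes = {i: 1 for i in clusters}
    merges = []
    next_id = len(dist)
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((dij, clusters[i] | clusters[j]))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dnew = (
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            ) ** 0.5
            d[(k, new)] = dnew
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[new] = merges[-1][1]
        sizes[new] = len(merges[-1][1])
    return merges
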