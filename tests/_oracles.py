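"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: betweenness by
exhaustive path enumeration in exact rational arithmetic, and arrival /
connectivity recounts by brute-force scalar scans of raw trajectories.
"""

from fractions import Fraction
from itertools import permutations

import numpy as np
from shapely.geometry import Point


def all_shortest_paths_brute(nodes, edges, x, y):
    """All shortest directed x->y paths by DFS over simple paths."""
    adj = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
    best: list[list] = []
    best_len = [None]

    def dfs(path):
        cur = path[-1]
        if best_len[0] is not None and len(path) - 1 > best_len[0]:
            return
        if cur == y and len(path) > 1:
            length = len(path) - 1
            if best_len[0] is None or length < best_len[0]:
                best_len[0] = length
                best.clear()
            if length == best_len[0]:
                best.append(list(path))
            return
        for nxt in adj[cur]:
            if nxt not in path:
                dfs(path + [nxt])

    dfs([x])
    return best


def betweenness_brute(nodes, edges):
    """Exact directed betweenness: sum over ordered pairs x != y != i of
    (# shortest x->y paths through i) / (# shortest x->y paths)."""
    bc = {n: Fraction(0) for n in nodes}
    for x, y in permutations(nodes, 2):
        paths = all_shortest_paths_brute(nodes, edges, x, y)
        if not paths:
            continue
        sigma = len(paths)
        for i in nodes:
            if i == x or i == y:
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            bc[i] += Fraction(through, sigma)
    return bc


def arrivals_brute(ensemble, registry):
    """First-entry arrivals by a scalar scan of every particle and sample."""
    records = []
    for p in range(ensemble.n_particles):
        seen = set()
        for r in range(ensemble.n_records):
            if ensemble.status[p, r] != 0:  # not alive
                continue
            pt = Point(ensemble.lon[p, r], ensemble.lat[p, r])
            for site in registry:
                if site.mpa_id in seen:
                    continue
                if site.boundary.covers(pt):
                    seen.add(site.mpa_id)
                    records.append((p, ensemble.origin_mpa[p],
                                    site.mpa_id, r))
    return records


def connectivity_brute(records, released_per_origin, mpa_ids):
    """c, r-counts, d, selfr, subr recomputed from raw arrival tuples."""
    n = len(mpa_ids)
    pos = {m: k for k, m in enumerate(mpa_ids)}
    counts = np.zeros((n, n))
    r_counts = np.zeros(n)
    seen_pairs = set()
    for p, origin, visited, _ in records:
        r_counts[pos[visited]] += 1
        if (p, visited) not in seen_pairs:
            seen_pairs.add((p, visited))
            counts[pos[origin], pos[visited]] += 1
    c = np.zeros((n, n))
    for m, k in pos.items():
        rel = released_per_origin.get(m, 0)
        if rel:
            c[k] = counts[k] / rel
    total = r_counts.sum()
    d = r_counts / total if total > 0 else r_counts * 0.0
    selfr = np.zeros(n)
    subr = np.zeros(n)
    for k in range(n):
        row = c[k].sum()
        if row > 0:
            selfr[k] = c[k, k] / row
            subr[k] = (row - c[k, k]) / row
    return c, r_counts, d, selfr, subr
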