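"""Independent reference implementations used only for cross-checking.

Each oracle re-derives a result by a different route than the package:
naive flooding with networkx geodesics for the watershed, explicit step-up
for BH, dense matrix exponentials for heat smoothing, Floyd-Warshall for
geodesics, exhaustive contiguous-partition search for 1-D k-means, and the
paired t-test for the hemisphere ANOVA.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse.csgraph as csgraph
import scipy.stats

from sulcalpits.mesh import edge_graph, vertex_areas


def nx_graph(mesh):
    G = nx.Graph()
    v = mesh.vertices
    for a, b, c in mesh.faces:
        for i, j in ((a, b), (b, c), (c, a)):
            G.add_edge(int(i), int(j), weight=float(np.linalg.norm(v[i] - v[j])))
    return G


def brute_watershed(mesh, depth, th):
    """Naive filtered watershed: explicit member sets, geodesics recomputed
    per merge test.  Returns (partition frozensets, pit vertex per basin)."""
    depth = np.asarray(depth, dtype=float)
    G = nx_graph(mesh)
    n = mesh.n_vertices
    order = sorted(range(n), key=lambda v: (-depth[v], v))
    basin_id = {}          # vertex -> basin key
    members = {}           # basin key -> set of vertices
    pit = {}               # basin key -> (pit_vertex, pit_depth)
    alias = {}             # merged basin key -> surviving key

    def resolve(b):
        while b in alias:
            b = alias[b]
        return b

    next_id = 0
    for v in order:
        adj = []
        for u in G.neighbors(v):
            if u in basin_id:
                b = resolve(basin_id[u])
                if b not in adj:
                    adj.append(b)
        if not adj:
            basin_id[v] = next_id
            members[next_id] = {v}
            pit[next_id] = (v, depth[v])
            next_id += 1
            continue
        if len(adj) > 1:
            adj.sort(key=lambda b: (-pit[b][1], pit[b][0]))
            target = adj[0]
            for b in adj[1:]:
                ridge = pit[b][1] - depth[v]
                if ridge < th.thr:
                    dd = nx.dijkstra_path_length(G, pit[target][0], pit[b][0])
                    if dd < th.thd:
                        members[target] |= members[b]
                        del members[b]
                        del pit[b]
                        alias[b] = target
            basin_id[v] = target
            members[target].add(v)
        else:
            basin_id[v] = adj[0]
            members[adj[0]].add(v)

    # post-flood small-basin absorption, smallest area first
    va = vertex_areas(mesh)

    def areas():
        return {b: float(sum(va[list(m)])) for b, m in members.items()}

    def boundary(b1, b2):
        tot = 0.0
        for i, j, d in G.edges(data=True):
            bi = resolve(basin_id[i])
            bj = resolve(basin_id[j])
            if {bi, bj} == {b1, b2}:
                tot += d["weight"]
        return tot

    dead = set()
    while len(members) > 1:
        ar = areas()
        small = sorted(
            (b for b in members if ar[b] < th.tha and b not in dead),
            key=lambda b: (ar[b], pit[b][0]),
        )
        if not small:
            break
        b = small[0]
        nbrs = {}
        for i, j in G.edges():
            bi = resolve(basin_id[i])
            bj = resolve(basin_id[j])
            if bi == b and bj != b:
                nbrs[bj] = None
            elif bj == b and bi != b:
                nbrs[bi] = None
        if not nbrs:
            dead.add(b)
            continue
        scored = sorted(
            nbrs,
            key=lambda q: (boundary(b, q), pit[q][1], -pit[q][0]),
            reverse=True,
        )
        best = scored[0]
        keep, lose = (best, b) if pit[best][1] >= pit[b][1] else (b, best)
        members[keep] |= members[lose]
        del members[lose]
        del pit[lose]
        alias[lose] = keep

    parts = {frozenset(m) for m in members.values()}
    pits = {pit[b][0] for b in members}
    return parts, pits


def bh_stepup(p, m=None):
    """Benjamini-Hochberg step-up q-values by the textbook recursion."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = len(p) - rank_from_top
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return np.clip(q, 0.0, 1.0)


def heat_kernel_smooth(mesh, texture, total_time):
    """Exact heat diffusion via dense matrix exponential of -t M^{-1} S."""
    from sulcalpits.mesh import laplace_operators

    S, M = laplace_operators(mesh)
    A = -total_time * (S.toarray() / vertex_areas(mesh)[:, None])
    out = scipy.linalg.expm(A) @ np.asarray(texture, dtype=float)
    out = np.clip(out, 0.0, None)
    peak = out.max()
    return out / peak if peak > 0 else out


def floyd_warshall_distances(mesh):
    G = edge_graph(mesh)
    return csgraph.floyd_warshall(G.toarray(), directed=False)


def best_1d_kmeans(values, k):
    """Optimal 1-D k-means by exhaustive search over contiguous partitions
    of the sorted values (the optimum is always contiguous)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        wss = 0.0
        groups = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = values[a:b]
            wss += float(((seg - seg.mean()) ** 2).sum())
            groups.append(frozenset(seg.tolist()))
        if wss < best[0]:
            best = (wss, groups)
    return best[1]


def paired_t(left, right):
    """Paired t-test; F = t^2 is the one-within-factor RM-ANOVA statistic."""
    t, p = scipy.stats.ttest_rel(left, right)
    return float(t), float(p)
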