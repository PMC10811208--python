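"""Independent brute-force oracles used by the tests.

Deliberately naive (per-locus Python loops, path-length tree distances,
sort-based outlier selection) and kept free of any code path they check.
"""

from __future__ import annotations

import numpy as np


def naive_locus_stats(G_column, pic_variant="nei"):
    """Recount one locus column (list of codes, -1 missing) from scratch."""
    called = [g for g in G_column if g >= 0]
    n = len(called)
    if n == 0:
        return None
    alt = sum(called)
    p = alt / (2 * n)
    q = 1 - p
    ho = sum(1 for g in called if g == 1) / n
    he = 2 * p * q
    nei = 1 - p * p - q * q
    pic = nei if pic_variant == "nei" else nei - 2 * p * p * q * q
    maf = min(p, q)
    return {"p_alt": p, "maf": maf, "n_called": n, "ho": ho, "he": he,
            "nei": nei, "pic": pic}


def naive_site_pi(G_column):
    """Average pairwise difference over all called allele pairs at a site."""
    called = [g for g in G_column if g >= 0]
    c = 2 * len(called)
    if c < 2:
        return 0.0
    alt = sum(called)
    ref = c - alt
    return 2.0 * alt * ref / (c * (c - 1))


def naive_filter(columns, min_depth=4, max_missing=0.3, min_maf=0.01):
    """Hand-applied sequential filter on a list of per-locus dicts with keys
    'g' (genotype list) and 'd' (depth list). Returns surviving indices."""
    survivors = []
    for j, col in enumerate(columns):
        g = [(-1 if d < min_depth else x) for x, d in zip(col["g"], col["d"])]
        n = len(g)
        miss = sum(1 for x in g if x < 0) / n
        if miss > max_missing:
            continue
        called = [x for x in g if x >= 0]
        if not called:
            continue
        p = sum(called) / (2 * len(called))
        if min(p, 1 - p) < min_maf:
            continue
        survivors.append(j)
    return survivors


def random_additive_tree(rng, n_taxa):
    """Random binary tree with branch lengths; returns (labels, D, splits).

    D is the path-length (additive) distance matrix; splits is the set of
    non-trivial bipartitions, each a frozenset normalized to exclude the
    smallest label.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a star over three nodes and attach remaining taxa to random
    # edges; represent the tree as an adjacency map with branch lengths
    next_id = [n_taxa]
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    center = next_id[0]
    next_id[0] += 1
    for i in range(3):
        add_edge(i, center, rng.uniform(0.5, 2.0))
    for i in range(3, n_taxa):
        # pick a random existing edge, subdivide, hang taxon i
        all_edges = [(a, b) for a in edges for b in edges[a] if a < b]
        a, b = all_edges[rng.integers(len(all_edges))]
        w = edges[a][b]
        mid = next_id[0]
        next_id[0] += 1
        del edges[a][b]
        del edges[b][a]
        cut = rng.uniform(0.25, 0.75) * w
        add_edge(a, mid, cut)
        add_edge(mid, b, w - cut)
        add_edge(i, mid, rng.uniform(0.5, 2.0))

    def dijkstra(src):
        import heapq

        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in edges[u].items():
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        return dist

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = dijkstra(i)
        for j in range(n_taxa):
            D[i, j] = dist[j]
    D = (D + D.T) / 2.0  # remove float path-sum asymmetry

    # bipartitions: removing each internal edge splits the leaves
    splits = set()
    leaf_set = set(range(n_taxa))

    def reachable(start, blocked_edge):
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in edges[u]:
                if (u, v) == blocked_edge or (v, u) == blocked_edge:
                    continue
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    for a in edges:
        for b in edges[a]:
            if a < b:
                side = {x for x in reachable(a, (a, b)) if x in leaf_set}
                if 2 <= len(side) <= n_taxa - 2:
                    if 0 in side:
                        side = leaf_set - side
                    splits.add(frozenset(labels[i] for i in side))
    return labels, D, splits


def naive_top_intersection(z, r, top_fraction):
    """Sort-and-threshold double-ranking oracle for outlier selection."""
    z = np.asarray(z, float)
    r = np.asarray(r, float)
    keep = np.isfinite(z) & np.isfinite(r)
    tz = np.quantile(z[keep], 1 - top_fraction)
    tr = np.quantile(r[keep], 1 - top_fraction)
    return set(np.flatnonzero(keep & (z >= tz) & (r >= tr)).tolist())


def naive_bh(pvals):
    """Step-up Benjamini–Hochberg adjusted values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
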