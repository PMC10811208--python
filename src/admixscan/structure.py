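"""Distance-based phylogenetics, genomic relationships and PCA.

The tree builder is the classic Saitou–Nei neighbor-joining agglomeration on
genotype p-distances, with bootstrap support from locus resampling and
optional outgroup rooting. Relationship estimation uses the standard
allele-frequency-standardized GRM, and PCA is an eigendecomposition of the
double-centered relationship matrix.
"""

from __future__ import annotations

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .datamodel import GenotypeMatrix


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise p-distance d(i,j) = sum |g_i - g_j| / (2 m_ij) with pairwise
    deletion of missing genotypes (m_ij = loci called in both samples)."""
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    return _p_distance_array(gm.G, gm.sample_ids)


def _p_distance_array(G: np.ndarray, sample_ids) -> np.ndarray:
    called = (G >= 0).astype(np.float64)
    X = [((G == v) & (G >= 0)).astype(np.float64) for v in (0, 1, 2)]
    # sum over loci of |u - v| over the 3x3 genotype pairs
    diff = (
        X[0] @ X[1].T + X[1] @ X[0].T + X[1] @ X[2].T + X[2] @ X[1].T
        + 2.0 * (X[0] @ X[2].T + X[2] @ X[0].T)
    )
    shared = called @ called.T
    n = G.shape[0]
    if (shared[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"samples {sample_ids[i]} and {sample_ids[j]} share no called loci"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / (2.0 * shared)
    np.fill_diagonal(d, 0.0)
    return d


def check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: np.ndarray, labels: list[str]) -> Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero. Ties in the Q-criterion are
    broken deterministically by the lexicographically smallest pair of
    representative (minimum descendant) leaf labels. Returns an unrooted
    tree, represented with a trifurcating root.
    """
    d = check_distance_matrix(d)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("labels must match matrix size")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dist = d.astype(float).copy()
    clades = [Clade(name=lab) for lab in labels]
    reps = list(labels)  # representative leaf label per active node
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        ci, cj = clades[i], clades[j]
        ci.branch_length = max(0.0, li)
        cj.branch_length = max(0.0, lj)
        new = Clade(clades=[ci, cj])
        clades.append(new)
        reps.append(min(reps[i], reps[j]))
        return len(clades) - 1

    while len(active) > 3:
        r = len(active)
        sub = dist[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                key = (q[a, b], tuple(sorted((reps[active[a]], reps[active[b]]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lj = dij - li
        k = join(i, j, li, lj)
        # distances from the new node to the remaining active nodes
        newdist = np.zeros(k)
        for c in active:
            if c in (i, j):
                continue
            newdist[c] = 0.5 * (dist[i, c] + dist[j, c] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[k, :k] = newdist
        dist[:k, k] = newdist
        active = [c for c in active if c not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    order = sorted(range(3), key=lambda t: reps[[i, j, k][t]])
    children = [clades[[i, j, k][t]] for t in order]
    for child, bl in zip(children, [[li, lj, lk][t] for t in order]):
        child.branch_length = max(0.0, bl)
    root = Clade(clades=children)
    return Tree(root=root, rooted=False)


def tree_leaf_names(tree: Tree) -> list[str]:
    return [t.name for t in tree.get_terminals()]


def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an (unrooted) tree, each normalized
    to the side not containing the lexicographically smallest leaf."""
    leaves = set(tree_leaf_names(tree))
    ref = min(leaves)
    parts = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(side)
    return parts


def patristic_distances(tree: Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix (oracle for additivity checks)."""
    n = len(labels)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = tree.distance(labels[a], labels[b])
    return out


def bootstrap_support(
    gm: GenotypeMatrix, n_reps: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree from the full data with bootstrap support on internal edges.

    Loci are resampled with replacement ``n_reps`` times; support for each
    internal bipartition of the full-data tree is the fraction of replicate
    trees containing it, stored in ``clade.confidence`` in [0, 1].
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(p_distance(gm), gm.sample_ids)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    m = gm.n_loci
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        d_rep = _p_distance_array(gm.G[:, cols], gm.sample_ids)
        rep_tree = neighbor_joining(d_rep, gm.sample_ids)
        rep_parts = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    leaves = set(gm.sample_ids)
    ref = min(leaves)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if ref in side:
            side = frozenset(leaves - side)
        if side in counts:
            clade.confidence = counts[side] / n_reps
    return tree


def root_with_outgroup(tree: Tree, outgroup_label: str) -> Tree:
    """Root the tree on the edge leading to the outgroup leaf."""
    names = tree_leaf_names(tree)
    if outgroup_label not in names:
        raise ValueError(f"outgroup {outgroup_label!r} not among leaves {names}")
    import copy

    rooted = copy.deepcopy(tree)
    rooted.root_with_outgroup({"name": outgroup_label})
    rooted.rooted = True
    return rooted


# ---------------------------------------------------------------------------
# GRM / PCA
# ---------------------------------------------------------------------------

def grm(gm: GenotypeMatrix) -> np.ndarray:
    """Allele-frequency-standardized genomic relationship matrix.

    G_ij = (1/m_ij) sum_l (g_il - 2 p_l)(g_jl - 2 p_l) / (2 p_l (1 - p_l)),
    with missing genotypes contributing zero and shrinking that pair's
    locus count m_ij. Monomorphic loci must be filtered upstream.
    """
    from .diversity import allele_frequency

    p = allele_frequency(gm)
    if np.isnan(p).any() or ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("GRM requires polymorphic loci (filter MAF upstream)")
    called = gm.called
    M = np.where(called, gm.G, 0).astype(float) - 2.0 * p[None, :]
    M[~called] = 0.0
    M /= np.sqrt(2.0 * p * (1.0 - p))[None, :]
    shared = called.astype(float) @ called.astype(float).T
    if (shared == 0).any():
        raise ValueError("a sample pair shares no called loci")
    return (M @ M.T) / shared


def pca(K: np.ndarray, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a symmetric relationship matrix.

    The matrix is double-centered, then eigendecomposed; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) (zero-mean by construction),
    components ordered by descending eigenvalue, and the variance proportion
    of each axis is its eigenvalue over the sum of positive eigenvalues.
    Sign convention: the first nonzero loading of each axis is positive.
    """
    from scipy.linalg import eigh

    K = check_distance_matrix(K)  # symmetry/finiteness checks
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ K @ H
    vals, vecs = eigh(Kc)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals[vals > 1e-10]
    varprop = np.where(vals > 1e-10, vals / pos.sum() if len(pos) else np.nan, 0.0)
    k = min(n_components, n)
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    for axis in range(k):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords, varprop[:k]
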