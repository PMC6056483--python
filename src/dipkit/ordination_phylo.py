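"""Ordination (PCA, classical MDS) and neighbor-joining trees.

PCA operates on individual-level dosage matrices: loci are mean-centered
(mean imputation for missing dosages) but *not* variance-scaled, and scores
come from an SVD with a fixed sign convention, so output is deterministic.
Classical (Torgerson) MDS double-centers the squared distance matrix and
embeds with the top eigenpairs.  Neighbor joining follows Saitou & Nei with
the Studier-Keppler criterion, lexicographic tie-breaking and clamping of
negative branch lengths (deficit shifted to the sibling edge so the joined
pair's distance is preserved), which makes trees bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, svd

from .core import DistanceMatrix, GenotypeMatrix


@dataclass
class Ordination:
    coordinates: np.ndarray  # entities x components
    explained_pct: np.ndarray  # per retained component, % of total
    entity_labels: list[str]
    method: str  # {"pca", "mds"}
    degenerate: bool = False
    dropped_negative_eig_mass: float = 0.0  # MDS diagnostic

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.entity_labels):
            raise ValueError("coordinate rows != entity count")
        if (self.explained_pct < -1e-9).any():
            raise ValueError("explained percentages must be nonnegative")


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its loading vector has nonnegative sum."""
    for k in range(loadings.shape[0]):
        s = loadings[k].sum()
        if s < 0 or (s == 0 and loadings[k][np.argmax(np.abs(loadings[k]))] < 0):
            loadings[k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 3) -> Ordination:
    """Principal components of the individuals x loci dosage matrix.

    Missing dosages are mean-imputed per locus; columns are mean-centered
    only.  ``explained_pct`` is 100 * eigenvalue / total over *all* nonzero
    components, so the retained percentages sum to at most 100.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 individuals")
    X = gm.dosage.astype(float)
    typed = gm.typed_mask()
    with np.errstate(invalid="ignore"):
        col_mean = np.where(typed, X, np.nan)
        col_mean = np.nanmean(col_mean, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    X = np.where(typed, X, col_mean[None, :]) - col_mean[None, :]
    U, s, Vt = svd(X, full_matrices=False)
    eigvals = s**2
    total = eigvals.sum()
    if total <= 1e-12:
        warnings.warn("zero total variance; degenerate PCA")
        k = min(n_components, X.shape[1])
        return Ordination(np.zeros((gm.n_samples, k)), np.zeros(k), list(gm.samples),
                          "pca", degenerate=True)
    rank = int((eigvals > eigvals[0] * 1e-12).sum())
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = rank
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].copy()
    scores, _ = _fix_signs(scores, loadings)
    pct = 100.0 * eigvals[:n_components] / total
    return Ordination(scores, pct, list(gm.samples), "pca")


def classical_mds(dm: DistanceMatrix, k: int = 2) -> Ordination:
    """Torgerson metric MDS of a symmetric nonnegative distance matrix."""
    D = np.asarray(dm.values, dtype=float)
    if (D < 0).any():
        raise ValueError("MDS requires nonnegative distances (clamp Fst first)")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, vals[0] * 1e-12) if vals[0] > 0 else vals > 1e-12
    n_pos = int(pos.sum())
    neg_mass = float(-vals[vals < 0].sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = n_pos
    if k == 0:
        return Ordination(np.zeros((n, 1)), np.zeros(1), list(dm.labels), "mds",
                          degenerate=True, dropped_negative_eig_mass=neg_mass)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    coords, _ = _fix_signs(coords, coords.T.copy())
    pos_total = vals[pos].sum()
    pct = 100.0 * vals[:k] / pos_total
    return Ordination(coords, pct, list(dm.labels), "mds",
                      dropped_negative_eig_mass=neg_mass)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class NJTree:
    """Unrooted binary tree; ``root`` is the final degree-3 internal node."""

    root: TreeNode
    labels: list[str]

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.label)
            for c, _ in node.children:
                walk(c)

        walk(self.root)
        return out

    def tip_distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (for additivity checks)."""
        dists: dict[str, dict[str, float]] = {}

        def below(node: TreeNode, acc: float) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, acc)]
            out = []
            for c, bl in node.children:
                out.extend(below(c, acc + bl))
            return out

        groups = [below(c, bl) for c, bl in self.root.children]
        labels = sorted(l for g in groups for l, _ in g)
        idx = {l: i for i, l in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))

        # distances within a child subtree, found recursively
        def within(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, 0.0)]
            lists = []
            for c, bl in node.children:
                lists.append([(l, d + bl) for l, d in within(c)])
            for a in range(len(lists)):
                for b in range(a + 1, len(lists)):
                    for la, da in lists[a]:
                        for lb, db in lists[b]:
                            m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = da + db
            return [t for lst in lists for t in lst]

        within(self.root)
        return DistanceMatrix(labels, m, kind="fst")


def nj_tree(dm: DistanceMatrix) -> NJTree:
    """Neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined; among equal-Q pairs the one whose (smallest-leaf-label,
    smallest-leaf-label) key is lexicographically least wins.  A negative
    limb length is clamped to 0 and its deficit moved to the sibling limb,
    preserving d(i,j).
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[int, TreeNode] = {i: TreeNode(label=l) for i, l in enumerate(labels)}
    key: dict[int, str] = {i: l for i, l in enumerate(labels)}
    d: dict[frozenset, float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d[frozenset((i, j))] = float(dm.values[i, j])
    active = sorted(nodes)
    next_id = len(labels)

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[frozenset((i, k))] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[frozenset((i, j))] - R[i] - R[j]
                tie = tuple(sorted((key[i], key[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = d[frozenset((i, j))]
        li = dij / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = u
        key[next_id] = min(key[i], key[j])
        for k in active:
            if k in (i, j):
                continue
            d[frozenset((next_id, k))] = 0.5 * (
                d[frozenset((i, k))] + d[frozenset((j, k))] - dij
            )
        active = sorted([k for k in active if k not in (i, j)] + [next_id])
        next_id += 1

    i, j, k = active
    dij = d[frozenset((i, j))]
    dik = d[frozenset((i, k))]
    djk = d[frozenset((j, k))]
    li = max(0.0, (dij + dik - djk) / 2)
    lj = max(0.0, (dij + djk - dik) / 2)
    lk = max(0.0, (dik + djk - dij) / 2)
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return NJTree(root=root, labels=labels)
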