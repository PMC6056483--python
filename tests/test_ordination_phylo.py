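"""PCA, classical MDS and neighbor joining."""

import itertools

import numpy as np
import pytest

from dipkit import ordination_phylo as op
from dipkit.core import DistanceMatrix, GenotypeMatrix, LocusDef, MISSING


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_explained_pct_sums_to_100(self, small_panel):
        ord_ = op.pca_genotypes(small_panel, n_components=small_panel.n_loci)
        assert ord_.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_identical_individuals_degenerate(self):
        gm = GenotypeMatrix(["a", "b"], ["P", "P"], [LocusDef("L")],
                            np.array([[1], [1]]))
        with pytest.warns(UserWarning, match="degenerate"):
            ord_ = op.pca_genotypes(gm, 1)
        assert ord_.degenerate
        assert (ord_.coordinates == 0).all()

    def test_sample_order_invariance(self, small_panel):
        ord_ = op.pca_genotypes(small_panel, 2)
        perm = np.random.default_rng(0).permutation(small_panel.n_samples)
        shuffled = GenotypeMatrix(
            [small_panel.samples[i] for i in perm],
            [small_panel.populations[i] for i in perm],
            small_panel.loci, small_panel.dosage[perm])
        ord_2 = op.pca_genotypes(shuffled, 2)
        back = np.empty_like(ord_2.coordinates)
        back[perm] = ord_2.coordinates
        np.testing.assert_allclose(back, ord_.coordinates, atol=1e-8)

    def test_missing_mean_imputed(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.5, (30, 10)).astype(np.int8)
        dosage[0, 0] = MISSING
        gm = GenotypeMatrix([f"s{i}" for i in range(30)], ["P"] * 30,
                            [LocusDef(f"L{j}") for j in range(10)], dosage)
        ord_ = op.pca_genotypes(gm, 2)
        assert np.isfinite(ord_.coordinates).all()

    def test_cluster_separation_on_preset(self, preset_panel):
        """PC1-PC2 separates the 4 clusters (positive silhouette), and the
        admixed Central-Asian individuals sit between the East-Asian and
        European centroids on PC1."""
        from sklearn.metrics import silhouette_score
        gm, _, _, cfg = preset_panel
        assign = cfg.population_cluster()
        labels = np.array([assign[p] for p in gm.populations])
        ord_ = op.pca_genotypes(gm, 2)
        assert silhouette_score(ord_.coordinates, labels) > 0.25
        pc1 = ord_.coordinates[:, 0]
        ea = pc1[labels == "EastAsian"].mean()
        eu = pc1[labels == "European"].mean()
        ca = pc1[labels == "CentralAsian"].mean()
        assert min(ea, eu) < ca < max(ea, eu)


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------


class TestMds:
    def test_planar_points_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.random((4, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ord_ = op.classical_mds(DistanceMatrix(list("ABCD"), d, "fst"), k=2)
        x = ord_.coordinates
        d_hat = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d_hat, d, atol=1e-8)

    def test_zero_matrix_degenerate(self):
        dm = DistanceMatrix(list("ABC"), np.zeros((3, 3)), "fst")
        with pytest.warns(UserWarning):
            ord_ = op.classical_mds(dm, k=2)
        assert (ord_.coordinates == 0).all()

    def test_preset_theta_matrix_recovers_clusters(self, preset_panel):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score
        from dipkit.differentiation import fst_matrix
        gm, _, _, cfg = preset_panel
        dm = fst_matrix(gm).clamped()
        ord_ = op.classical_mds(dm, k=2)
        assign = cfg.population_cluster()
        truth = [assign[p] for p in ord_.entity_labels]
        pred = KMeans(4, n_init=10, random_state=0).fit_predict(ord_.coordinates)
        assert adjusted_rand_score(truth, pred) > 0.9

    def test_da_and_fst_mds_partitions_agree(self, preset_panel):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score
        from dipkit.differentiation import da_matrix, fst_matrix
        gm = preset_panel[0]
        m1 = op.classical_mds(fst_matrix(gm).clamped(), k=2)
        m2 = op.classical_mds(da_matrix(gm.allele_frequencies()), k=2)
        p1 = KMeans(4, n_init=10, random_state=0).fit_predict(m1.coordinates)
        p2 = KMeans(4, n_init=10, random_state=0).fit_predict(m2.coordinates)
        assert adjusted_rand_score(p1, p2) > 0.8


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def random_additive_matrix(n: int, rng) -> tuple[DistanceMatrix, list[str]]:
    """Distance matrix generated from a random binary tree with positive
    branch lengths (hence exactly additive)."""
    labels = [f"T{i}" for i in range(n)]
    # random topology: sequential taxon insertion on random edges
    import dendropy
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=__import__("random").Random(int(rng.integers(2**31))))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = labels[i]
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, m, "fst"), labels


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(list("ABC"),
                            np.array([[0., 2, 3], [2, 0, 4], [3, 4, 0]]), "fst")
        tree = op.nj_tree(dm)
        lengths = {c.label: bl for c, bl in tree.root.children}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_additive_matrices_recovered_exactly(self, n):
        rng = np.random.default_rng(n * 13)
        dm, labels = random_additive_matrix(n, rng)
        tree = op.nj_tree(dm)
        td = tree.tip_distance_matrix()
        order = [td.labels.index(l) for l in labels]
        np.testing.assert_allclose(td.values[np.ix_(order, order)], dm.values,
                                   atol=1e-10)

    def test_five_taxa_matches_exhaustive_search(self):
        """NJ topology equals the minimum-length topology over all 15
        unrooted 5-taxon trees with least-squares branch lengths."""
        rng = np.random.default_rng(99)
        dm, labels = random_additive_matrix(5, rng)
        best_split, _ = exhaustive_best_topology(dm)
        nj_splits = tree_splits(op.nj_tree(dm))
        assert best_split <= nj_splits

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            op.nj_tree(DistanceMatrix(["A", "B"], np.array([[0., 1], [1, 0]]), "fst"))

    def test_agrees_with_skbio_on_random_matrix(self):
        """Topology cross-check against an independent NJ implementation."""
        import skbio
        from dipkit.io_formats import read_newick, write_newick
        rng = np.random.default_rng(17)
        pts = rng.random((7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"T{i}" for i in range(7)]
        ours = read_newick(write_newick(op.nj_tree(DistanceMatrix(labels, d, "fst"))))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        assert ours.compare_rfd(theirs) == 0.0


def tree_splits(tree: op.NJTree) -> set[frozenset]:
    """Nontrivial bipartitions (as the smaller side's leaf set)."""
    all_leaves = set(tree.leaf_labels())
    splits = set()

    def walk(node, acc):
        if node.is_leaf:
            return {node.label}
        below = set()
        for c, _ in node.children:
            below |= walk(c, acc)
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            splits.add(frozenset(below if len(below) <= len(other) else other))
        return below

    walk(tree.root, set())
    return splits


def exhaustive_best_topology(dm: DistanceMatrix):
    """Least-squares fit of every unrooted 5-taxon topology; returns the
    splits and total length of the shortest tree."""
    labels = dm.labels
    n = len(labels)
    assert n == 5
    best = None
    # every unrooted binary 5-taxon topology is defined by its two
    # nontrivial splits {a,b}|rest and {c,d}|rest sharing no taxon
    for pair1 in itertools.combinations(range(n), 2):
        rest = [i for i in range(n) if i not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            splits = [set(pair1), set(pair2)]
            edges = _topology_edges(n, splits)
            total = _ls_total_length(dm.values, edges, n)
            if total is None:
                continue
            key = (frozenset(frozenset(labels[i] for i in s) for s in splits))
            if best is None or total < best[1] - 1e-12:
                best = (key, total)
    return best


def _topology_edges(n, splits):
    """Edge list as leaf-membership vectors for a 5-taxon tree with the two
    given cherries."""
    a, b = sorted(splits[0])
    c, d = sorted(splits[1])
    (e,) = set(range(n)) - splits[0] - splits[1]
    # edges: 5 pendant + 2 internal (cherry1-internal, cherry2-internal)
    edges = []
    for leaf in range(n):
        v = np.zeros(n)
        v[leaf] = 1
        edges.append(v)
    v1 = np.zeros(n)
    v1[[a, b]] = 1
    v2 = np.zeros(n)
    v2[[c, d]] = 1
    edges.extend([v1, v2])
    return edges


def _ls_total_length(D, edges, n):
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for c, v in enumerate(edges):
            A[r, c] = 1.0 if v[i] != v[j] else 0.0
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef.sum())
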