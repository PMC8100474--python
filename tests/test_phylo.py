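"""D_A closed forms, NJ consistency on additive matrices, independent NJ
oracle (dendropy), Newick round-trips, bootstrap supports."""

import io

import dendropy
import numpy as np
import pytest

from herdchar import (
    BaldingNicholsSpec,
    PopDistanceMatrix,
    bootstrap_tree,
    da_matrix,
    nei_da_pair,
    neighbor_joining,
    simulate_balding_nichols,
    write_newick,
)

from conftest import make_dataset


# --- D_A -------------------------------------------------------------------

def test_da_identical_profiles_zero():
    x = [np.array([0.3, 0.7]), np.array([0.9, 0.1])]
    assert nei_da_pair(x, x) == pytest.approx(0.0)


def test_da_disjoint_fixation_one():
    x = [np.array([1.0, 0.0])] * 4
    y = [np.array([0.0, 1.0])] * 4
    assert nei_da_pair(x, y) == pytest.approx(1.0)


def test_da_hand_computed_single_locus():
    x = [np.array([1.0, 0.0])]
    y = [np.array([0.5, 0.5])]
    assert nei_da_pair(x, y) == pytest.approx(1 - np.sqrt(0.5))


def test_da_undefined_locus_dropped():
    x = [np.array([0.5, 0.5]), np.array([np.nan, np.nan])]
    y = [np.array([0.5, 0.5]), np.array([0.2, 0.8])]
    assert nei_da_pair(x, y) == pytest.approx(0.0)


def test_da_matrix_duplicated_population_near_zero():
    rng = np.random.default_rng(31)
    g = rng.binomial(2, rng.uniform(0.1, 0.5, 600), size=(40, 600)).astype(np.int8)
    ds = make_dataset(g, ["a"] * 20 + ["b"] * 20)  # same pool, two labels
    dm = da_matrix(ds)
    assert dm.d[0, 1] < 0.01


def test_da_matrix_invariant_to_sample_order(bn_three_pops):
    rng = np.random.default_rng(32)
    perm = rng.permutation(bn_three_pops.n_samples)
    d1 = da_matrix(bn_three_pops)
    d2 = da_matrix(bn_three_pops.subset(sample_idx=perm))
    order = [d2.labels.index(l) for l in d1.labels]
    assert np.allclose(d1.d, d2.d[np.ix_(order, order)])


def test_da_monotone_in_differentiation():
    hits = 0
    for seed in range(10):
        lo = simulate_balding_nichols(
            BaldingNicholsSpec(n_pops=2, n_per_pop=30, n_loci=1000, fst=0.05, seed=seed)
        )
        hi = simulate_balding_nichols(
            BaldingNicholsSpec(n_pops=2, n_per_pop=30, n_loci=1000, fst=0.3, seed=seed)
        )
        if da_matrix(hi).d[0, 1] > da_matrix(lo).d[0, 1]:
            hits += 1
    assert hits >= 9


# --- Neighbor joining ------------------------------------------------------

def _random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree topology with positive branch lengths;
    returns (leaf labels, pairwise path-distance matrix, splits)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # grow by sequential leaf attachment onto random edges
    # represent tree as adjacency {node: {nbr: length}}
    adj = {0: {}, 1: {}}
    _connect(adj, 0, 1, rng.uniform(0.1, 1.0))
    next_node = 2
    internal = n_taxa  # internal ids start above leaf ids
    edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = internal
        internal += 1
        adj[mid] = {}
        cut = rng.uniform(0.2, 0.8) * w
        _connect(adj, u, mid, cut)
        _connect(adj, mid, v, w - cut)
        adj[leaf] = {}
        _connect(adj, mid, leaf, rng.uniform(0.1, 1.0))
        edges.remove((u, v))
        edges += [(u, mid), (mid, v), (mid, leaf)]
    # path distances between leaves by BFS
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n_taxa):
            d[i, j] = dist[j]
    return labels, d


def _connect(adj, u, v, w):
    adj[u][v] = w
    adj[v][u] = w


@pytest.mark.parametrize("n_taxa", [4, 5, 7])
def test_nj_exact_on_additive_matrices(n_taxa):
    rng = np.random.default_rng(n_taxa)
    labels, d = _random_additive_tree(n_taxa, rng)
    tree = neighbor_joining(PopDistanceMatrix(labels, d))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            assert tree.path_distance(labels[i], labels[j]) == pytest.approx(
                d[i, j], abs=1e-9
            )


def test_nj_three_taxa_closed_form():
    labels = ["a", "b", "c"]
    d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    tree = neighbor_joining(PopDistanceMatrix(labels, d))
    (na, la), (nb, lb), (nc, lc) = tree.root.children
    assert la == pytest.approx((3 + 4 - 5) / 2)
    assert lb == pytest.approx((3 + 5 - 4) / 2)
    assert lc == pytest.approx((4 + 5 - 3) / 2)


def test_nj_matches_dendropy_topology():
    """Independent oracle: dendropy's NJ on the same random matrices."""
    rng = np.random.default_rng(33)
    for _ in range(5):
        n = 6
        base = rng.uniform(0.2, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(PopDistanceMatrix(labels, d))
        csv = "," + ",".join(labels) + "\n"
        for i in range(n):
            csv += labels[i] + "," + ",".join(str(x) for x in d[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(labels)
        )
        ref = pdm.nj_tree()
        ref_sides = set()
        all_l = set(labels)
        for e in ref.preorder_edge_iter():
            if e.head_node.parent_node is None:
                continue
            clade = {t.taxon.label for t in e.head_node.leaf_iter()}
            if 1 < len(clade) < n - 1:
                side = clade if labels[0] not in clade else all_l - clade
                ref_sides.add(frozenset(side))
        assert mine.bipartitions() == ref_sides


def test_nj_validation_errors():
    with pytest.raises(ValueError):
        PopDistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))
    with pytest.raises(ValueError):
        neighbor_joining(PopDistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


# --- bootstrap + Newick ----------------------------------------------------

@pytest.fixture(scope="module")
def two_clade_ds():
    """Two deeply split clades of two close populations each."""
    rng = np.random.default_rng(34)
    p = rng.uniform(0.1, 0.9, 400)
    def drift(center, scale, n):
        pk = np.clip(center + rng.normal(0, scale, center.size), 0.02, 0.98)
        return rng.binomial(2, pk, size=(n, center.size)).astype(np.int8)
    left = np.clip(p - 0.3, 0.02, 0.98)
    right = np.clip(p + 0.3, 0.02, 0.98)
    g = np.vstack(
        [drift(left, 0.02, 15), drift(left, 0.02, 15),
         drift(right, 0.02, 15), drift(right, 0.02, 15)]
    )
    pops = ["L1"] * 15 + ["L2"] * 15 + ["R1"] * 15 + ["R2"] * 15
    return make_dataset(g, pops)


def test_bootstrap_strong_clade_support(two_clade_ds):
    tree = bootstrap_tree(two_clade_ds, n_reps=100, seed=1)
    supports = {
        frozenset(node.leaves()): node.support
        for node in tree.internal_nodes()
        if node.support is not None
    }
    clade = [s for k, s in supports.items() if k in (frozenset({"L1", "L2"}), frozenset({"R1", "R2"}))]
    assert clade and min(clade) >= 95


def test_bootstrap_deterministic(two_clade_ds):
    t1 = bootstrap_tree(two_clade_ds, n_reps=30, seed=7)
    t2 = bootstrap_tree(two_clade_ds, n_reps=30, seed=7)
    assert t1.newick() == t2.newick()


def test_bootstrap_zero_reps_has_no_supports(two_clade_ds):
    tree = bootstrap_tree(two_clade_ds, n_reps=0)
    assert all(n.support is None for n in tree.internal_nodes())


def test_newick_roundtrip_via_dendropy(tmp_path, two_clade_ds):
    tree = bootstrap_tree(two_clade_ds, n_reps=20, seed=2)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    text = path.read_text()
    assert text.strip().endswith(";")
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert {t.label for t in parsed.taxon_namespace} == set(tree.labels)
    # branch lengths survive the round trip
    pdm = parsed.phylogenetic_distance_matrix()
    tns = {t.label: t for t in parsed.taxon_namespace}
    for a in tree.labels[:2]:
        for b in tree.labels[2:]:
            assert pdm.distance(tns[a], tns[b]) == pytest.approx(
                tree.path_distance(a, b), abs=1e-9
            )
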