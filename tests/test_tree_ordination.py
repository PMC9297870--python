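import numpy as np
import pytest

from dupepi.genotypes import AlleleFreqTable, allele_frequencies
from dupepi.tree_ordination import (
    bootstrap_tree,
    neighbor_joining,
    pca_individuals,
    prevosti_distance,
    prevosti_distance_matrix,
)
from dupepi.synthetic_data import SimulationConfig, simulate_ssr_dataset

from conftest import make_matrix


def freq_table(freqs_by_locus, pops):
    """freqs_by_locus: list of (n_pops, n_alleles) arrays."""
    return AlleleFreqTable(
        populations=pops,
        loci=[f"L{j+1}" for j in range(len(freqs_by_locus))],
        alleles=[np.arange(f.shape[1]) + 100 for f in freqs_by_locus],
        freqs=[np.asarray(f, float) for f in freqs_by_locus],
        copies=[np.full(len(pops), 10.0) for _ in freqs_by_locus],
    )


# ----------------------------------------------------------------------
# Prevosti
# ----------------------------------------------------------------------
def test_identical_frequencies_zero_distance():
    f = freq_table([np.array([[0.5, 0.5], [0.5, 0.5]])], ["x", "y"])
    assert prevosti_distance(f, "x", "y") == 0.0


def test_fixed_different_alleles_distance_one():
    f = freq_table(
        [np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0, 0.0], [0.0, 1.0]])],
        ["x", "y"],
    )
    assert prevosti_distance(f, "x", "y") == 1.0


def test_hand_computed_example():
    # 2 loci: x = {(0.5, 0.5), (1, 0)}, y = {(0.25, 0.75), (0.5, 0.5)}
    f = freq_table(
        [
            np.array([[0.5, 0.5], [0.25, 0.75]]),
            np.array([[1.0, 0.0], [0.5, 0.5]]),
        ],
        ["x", "y"],
    )
    assert prevosti_distance(f, "x", "y") == pytest.approx(0.375)


def test_distance_matrix_symmetric_zero_diagonal():
    cfg = SimulationConfig(n_populations=5, f_st=0.1, seed=8)
    _, gm = simulate_ssr_dataset(cfg)
    d = prevosti_distance_matrix(allele_frequencies(gm))
    assert np.allclose(d, d.T)
    assert np.all(np.diag(d) == 0)
    assert d.min() >= 0 and d.max() <= 1


def test_no_shared_locus_is_error():
    f = freq_table([np.array([[1.0, 0.0], [0.0, 1.0]])], ["x", "y"])
    f.copies[0][1] = 0.0
    with pytest.raises(ValueError, match="shared"):
        prevosti_distance_matrix(f)


# ----------------------------------------------------------------------
# neighbour joining
# ----------------------------------------------------------------------
def tree_distances(root):
    """Leaf-to-leaf path lengths of a tree."""
    import itertools

    paths = {}

    def walk(node, dist, acc):
        acc = acc + [(node, dist)]
        if node.is_leaf:
            paths[node.name] = acc
        for ch in node.children:
            walk(ch, dist + ch.length, acc)

    walk(root, 0.0, [])
    out = {}
    for a, b in itertools.combinations(sorted(paths), 2):
        pa = {id(n): d for n, d in paths[a]}
        shared = [d for n, d in paths[b] if id(n) in pa]
        da = paths[a][-1][1]
        db = paths[b][-1][1]
        out[(a, b)] = da + db - 2 * max(shared)
    return out


def test_three_taxon_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = neighbor_joining(d, ["A", "B", "C"])
    lengths = {lf.name: lf.length for lf in tree.leaves()}
    # three-point formulas: a = (dAB + dAC - dBC)/2, etc.
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_four_taxon_additive_recovery():
    # tree: ((A:1,B:2):1,C:3,D:4) — additive distances
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        float,
    )
    tree = neighbor_joining(d, ["A", "B", "C", "D"])
    assert frozenset({"A", "B"}) in tree.bipartitions()
    td = tree_distances(tree)
    for (a, b), expect in {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
        ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
    }.items():
        assert td[(a, b)] == pytest.approx(expect)


def test_random_additive_trees_recovered():
    rng = np.random.default_rng(0)
    for n_leaves in (4, 5, 6, 8):
        for _ in range(3):
            # random binary tree via random pair joins, random positive lengths
            names = [f"T{i}" for i in range(n_leaves)]
            from dupepi.trees import TreeNode

            nodes = [TreeNode(nm) for nm in names]
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                a, b = nodes[j], nodes[i]
                for x in (a, b):
                    x.length = float(rng.uniform(0.5, 2.0))
                parent = TreeNode(children=[a, b])
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
            for x in nodes:
                x.length = float(rng.uniform(0.5, 2.0))
            truth = TreeNode(children=nodes)
            td = tree_distances(truth)
            labels = sorted({x for pair in td for x in pair})
            n = len(labels)
            d = np.zeros((n, n))
            for (a, b), v in td.items():
                ia, ib = labels.index(a), labels.index(b)
                d[ia, ib] = d[ib, ia] = v
            recon = neighbor_joining(d, labels)
            assert recon.bipartitions() == truth.bipartitions()
            rd = tree_distances(recon)
            for pair, v in td.items():
                assert rd[pair] == pytest.approx(v, abs=1e-9)


def test_equidistant_taxa_deterministic():
    d = np.ones((4, 4)) - np.eye(4)
    t1 = neighbor_joining(d, ["A", "B", "C", "D"])
    t2 = neighbor_joining(d, ["A", "B", "C", "D"])
    assert t1.bipartitions() == t2.bipartitions()
    assert frozenset({"A", "B"}) in t1.bipartitions()  # lowest-index pair joined first


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError):
        neighbor_joining(np.zeros((2, 2)), ["A", "B"])


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def test_identical_loci_full_support():
    block = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.5, 0.5]])
    f = freq_table([block.copy() for _ in range(6)], ["a", "b", "c", "d"])
    tree = bootstrap_tree(f, n_reps=50, seed=0)
    supports = [n.support for n in tree.postorder() if not n.is_leaf and n is not tree]
    assert supports and all(s == 100.0 for s in supports)


def test_two_cluster_bipartition_high_support():
    cfg = SimulationConfig(
        n_populations=4, individuals_per_population=(15, 15), n_loci=12,
        f_st=0.02, missing_rate=0.0, seed=41,
    )
    _, gm = simulate_ssr_dataset(cfg, seed=41)
    # graft strong divergence between {P01,P02} and {P03,P04}: shift half the loci
    data = gm.data.copy()
    rows = [i for i, p in enumerate(gm.populations) if p in ("P03", "P04")]
    data[rows, :6, :] += 1000  # disjoint allele sets at 6 loci
    gm2 = type(gm)(gm.individuals, gm.populations, gm.loci, data)
    tree = bootstrap_tree(allele_frequencies(gm2), n_reps=200, seed=2)
    node = tree.find_clade(frozenset({"P01", "P02"}))
    assert node is not None and node.support > 95


def test_bootstrap_seed_deterministic():
    cfg = SimulationConfig(n_populations=5, f_st=0.1, seed=9)
    _, gm = simulate_ssr_dataset(cfg)
    f = allele_frequencies(gm)
    t1 = bootstrap_tree(f, n_reps=100, seed=7)
    t2 = bootstrap_tree(f, n_reps=100, seed=7)
    s1 = sorted(n.support for n in t1.postorder() if n.support is not None)
    s2 = sorted(n.support for n in t2.postorder() if n.support is not None)
    assert s1 == s2


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
def test_mirror_genotypes_pc1_full_variance():
    gm = make_matrix([[(100, 100), (200, 200)], [(105, 105), (205, 205)]])
    _, pct = pca_individuals(gm)
    assert pct[0] == pytest.approx(100.0)


def test_pct_variance_sums_to_100():
    cfg = SimulationConfig(n_populations=3, f_st=0.1, seed=2)
    _, gm = simulate_ssr_dataset(cfg)
    _, pct = pca_individuals(gm)
    assert pct.sum() == pytest.approx(100.0)


def test_three_cluster_separation_on_pcs():
    cfg = SimulationConfig(
        n_populations=3, individuals_per_population=(20, 20), n_loci=20,
        f_st=0.15, f_is=0.0, missing_rate=0.0, seed=33,
    )
    _, gm = simulate_ssr_dataset(cfg, seed=33)
    coords, _ = pca_individuals(gm)
    from scipy.cluster.vq import kmeans2

    _, assign = kmeans2(coords[:, :2], 3, seed=1, minit="++")
    truth = np.array([gm.population_ids().index(p) for p in gm.populations])
    # best label permutation accuracy
    import itertools

    acc = max(
        (assign == np.array([perm[t] for t in truth])).mean()
        for perm in itertools.permutations(range(3))
    )
    assert acc > 0.9


def test_pca_single_individual_rejected():
    gm = make_matrix([[(100, 105)]])
    with pytest.raises(ValueError):
        pca_individuals(gm)
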