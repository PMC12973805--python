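import itertools

import numpy as np
import pytest
import skbio

import phylosym as ps
from phylosym import _treeops
from phylosym.errors import DegenerateTraitError, LabelError, SizeError


# ---------------------------------------------------------------------------
# independent oracles

def dendropy_rf(newick1, newick2):
    import dendropy
    from dendropy.calculate import treecompare
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


def leaf_sets(tree):
    """Rooted non-trivial clusters as frozensets of leaf names."""
    n = len(list(tree.tips()))
    out = []
    for node in tree.postorder():
        if node.is_tip() or node.parent is None:
            continue
        s = frozenset(t.name for t in node.tips())
        if 2 <= len(s) <= n - 1:
            out.append(s)
    return out


def brute_force_matching_cluster(t1, t2):
    c1, c2 = leaf_sets(t1), leaf_sets(t2)
    k = max(len(c1), len(c2))
    c1 = c1 + [frozenset()] * (k - len(c1))
    c2 = c2 + [frozenset()] * (k - len(c2))
    best = None
    for perm in itertools.permutations(range(k)):
        cost = sum(len(c1[i] ^ c2[perm[i]]) for i in range(k))
        best = cost if best is None else min(best, cost)
    return best


def unrooted_splits(tree):
    """Non-trivial unrooted splits as frozensets-of-frozensets of names."""
    names = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.postorder():
        if node.is_tip() or node.parent is None:
            continue
        s = frozenset(t.name for t in node.tips())
        if 2 <= len(s) <= len(names) - 2:
            out.add(frozenset([s, names - s]))
    return out


def split_mi(split1, split2, n):
    total = 0.0
    for x in split1:
        for y in split2:
            c = len(x & y)
            if c:
                total += (c / n) * np.log2(c * n / (len(x) * len(y)))
    return total


def brute_force_cid(t1, t2):
    names = frozenset(t.name for t in t1.tips())
    n = len(names)

    def entropy(split):
        return -sum((len(x) / n) * np.log2(len(x) / n) for x in split)

    s1, s2 = list(unrooted_splits(t1)), list(unrooted_splits(t2))
    h = sum(entropy(s) for s in s1) + sum(entropy(s) for s in s2)
    if not s1 or not s2:
        return h
    k = max(len(s1), len(s2))
    best = 0.0
    for perm in itertools.permutations(range(k)):
        total = 0.0
        for i in range(k):
            j = perm[i]
            if i < len(s1) and j < len(s2):
                total += split_mi(s1[i], s2[j], n)
        best = max(best, total)
    return h - 2 * best


# ---------------------------------------------------------------------------


class TestUpgma:
    def test_one_step_by_hand(self):
        d = skbio.DistanceMatrix(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
        )
        tree = ps.upgma_dendrogram(d)
        a = next(t for t in tree.tips() if t.name == "A")
        assert a.length == pytest.approx(0.5)
        # topology ((A,B),C)
        sisters = {t.name for t in a.parent.tips()}
        assert sisters == {"A", "B"}

    def test_equal_distances_equal_heights(self):
        d = skbio.DistanceMatrix(2 * (1 - np.eye(4)), ids=list("ABCD"))
        tree = ps.upgma_dendrogram(d)
        depths = {}
        for node in tree.preorder():
            base = depths.get(id(node.parent), 0.0)
            depths[id(node)] = base + (node.length or 0.0)
        tip_depths = [depths[id(t)] for t in tree.tips()]
        np.testing.assert_allclose(tip_depths, tip_depths[0])

    def test_two_labels_single_cherry(self):
        d = skbio.DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        tree = ps.upgma_dendrogram(d)
        assert {t.name for t in tree.tips()} == {"A", "B"}


class TestTreeMetricsBasics:
    def test_identical_trees_all_zero(self):
        t1 = skbio.TreeNode.read(["((A,B),(C,(D,E)));"])
        t2 = skbio.TreeNode.read(["((A,B),(C,(D,E)));"])
        assert ps.rf_distance(t1, t2) == 0
        assert ps.matching_cluster_distance(t1, t2) == 0
        assert ps.cid(t1, t2) == pytest.approx(0.0, abs=1e-12)

    def test_four_leaf_rf_is_two(self):
        t1 = skbio.TreeNode.read(["((A,B),(C,D));"])
        t2 = skbio.TreeNode.read(["((A,C),(B,D));"])
        assert ps.rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch(self):
        t1 = skbio.TreeNode.read(["((A,B),(C,D));"])
        t2 = skbio.TreeNode.read(["((A,B),(C,E));"])
        with pytest.raises(LabelError):
            ps.rf_distance(t1, t2)

    def test_caterpillar_vs_balanced_matches_oracles(self):
        t1 = skbio.TreeNode.read(["(((((A,B),C),D),E),F);"])
        t2 = skbio.TreeNode.read(["(((A,B),(C,D)),(E,F));"])
        assert ps.matching_cluster_distance(t1, t2) == \
            brute_force_matching_cluster(t1, t2)
        assert ps.cid(t1, t2) == pytest.approx(brute_force_cid(t1, t2))
        assert ps.rf_distance(t1, t2) == dendropy_rf(str(t1), str(t2))

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_random_pairs_match_oracles(self, n_leaves):
        labels = [f"L{i}" for i in range(n_leaves)]
        rng = np.random.default_rng(123)
        for _ in range(25):
            t1 = ps.random_tree(labels, seed=int(rng.integers(2**31 - 1)))
            t2 = ps.random_tree(labels, seed=int(rng.integers(2**31 - 1)))
            assert ps.rf_distance(t1, t2) == dendropy_rf(str(t1), str(t2))
            assert ps.matching_cluster_distance(t1, t2) == \
                brute_force_matching_cluster(t1, t2)
            assert ps.cid(t1, t2) == pytest.approx(brute_force_cid(t1, t2),
                                                   abs=1e-9)

    def test_metrics_nonnegative(self):
        rng = np.random.default_rng(7)
        labels = [f"L{i}" for i in range(8)]
        for _ in range(10):
            t1 = ps.random_tree(labels, seed=int(rng.integers(2**31 - 1)))
            t2 = ps.random_tree(labels, seed=int(rng.integers(2**31 - 1)))
            assert ps.rf_distance(t1, t2) >= 0
            assert ps.matching_cluster_distance(t1, t2) >= 0
            assert ps.cid(t1, t2) >= -1e-12


class TestRandomTree:
    def test_three_labels_forced_topology(self):
        for seed in range(5):
            t = ps.random_tree(["A", "B", "C"], seed=seed)
            assert {x.name for x in t.tips()} == {"A", "B", "C"}

    def test_four_label_uniformity(self):
        labels = ["A", "B", "C", "D"]
        ref = {}  # canonical split -> count
        rng = np.random.default_rng(99)
        counts = {}
        for _ in range(10_000):
            topo = _treeops.RandomTopology(4, rng)
            (split,) = topo.splits()
            counts[split] = counts.get(split, 0) + 1
        freqs = np.array(list(counts.values())) / 10_000
        assert len(freqs) == 3
        assert np.all(np.abs(freqs - 1 / 3) < 0.02)

    def test_seed_determinism(self):
        labels = [f"L{i}" for i in range(9)]
        a = ps.random_tree(labels, seed=5)
        b = ps.random_tree(labels, seed=5)
        assert str(a) == str(b)

    def test_too_few_labels(self):
        with pytest.raises(SizeError):
            ps.random_tree(["A", "B"])


class TestPhylosymbiosisTest:
    def test_identical_topology_smallest_p(self):
        host = ps.random_tree([f"L{i}" for i in range(9)], seed=3)
        res = ps.phylosymbiosis_test(host, host, metric="rf", n_random=199,
                                     seed=4)
        assert res.observed == 0
        # every null tree matching the host exactly is vanishingly rare
        assert res.p <= 2 / 200

    def test_normalized_is_observed_over_null_mean(self):
        host = ps.random_tree([f"L{i}" for i in range(8)], seed=11)
        dendro = ps.random_tree([f"L{i}" for i in range(8)], seed=12)
        res = ps.phylosymbiosis_test(host, dendro, metric="rf", n_random=99,
                                     seed=13)
        assert res.normalized == pytest.approx(res.observed / res.null_mean)

    def test_invariant_to_consistent_relabeling(self):
        labels = [f"L{i}" for i in range(8)]
        host = ps.random_tree(labels, seed=21)
        dendro = ps.random_tree(labels, seed=22)
        res1 = ps.phylosymbiosis_test(host, dendro, metric="rf",
                                      n_random=199, seed=5)
        mapping = {f"L{i}": f"Z{7 - i}" for i in range(8)}
        host2, dendro2 = host.copy(), dendro.copy()
        for t in list(host2.tips()) + list(dendro2.tips()):
            t.name = mapping[t.name]
        res2 = ps.phylosymbiosis_test(host2, dendro2, metric="rf",
                                      n_random=199, seed=5)
        assert res1.observed == res2.observed
        assert res1.p == res2.p


class TestBlombergsK:
    def test_star_tree_K_is_exactly_one(self):
        """On a star phylogeny V is proportional to I, so K = 1 for any
        trait, whatever its distribution."""
        star = skbio.TreeNode.read(["(A:1,B:1,C:1,D:1,E:1);"])
        rng = np.random.default_rng(0)
        for _ in range(5):
            trait = dict(zip("ABCDE", rng.normal(size=5)))
            res = ps.blombergs_k(star, trait, n_perm=19, seed=1)
            assert res.K == pytest.approx(1.0, abs=1e-10)

    def test_clade_structured_trait_has_high_K_and_low_p(self):
        tree = skbio.TreeNode.read(
            ["(((A:1,B:1):5,(C:1,D:1):5):1,((E:1,F:1):5,(G:1,H:1):5):1);"]
        )
        trait = {"A": 10, "B": 10.5, "C": 9.5, "D": 10.2,
                 "E": 0, "F": 0.4, "G": -0.3, "H": 0.1}
        res = ps.blombergs_k(tree, trait, n_perm=999, seed=2)
        assert res.K > 1.0
        assert res.p < 0.05

    def test_constant_trait_errors(self, balanced_tree):
        with pytest.raises(DegenerateTraitError):
            ps.blombergs_k(balanced_tree, {n: 1.0 for n in "ABCD"})

    def test_seed_reproducible(self, balanced_tree):
        trait = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 3.0}
        a = ps.blombergs_k(balanced_tree, trait, n_perm=99, seed=7)
        b = ps.blombergs_k(balanced_tree, trait, n_perm=99, seed=7)
        assert a.p == b.p and a.K == b.K
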