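import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import phylosym as ps
from phylosym.errors import (
    DegenerateSampleError,
    DesignError,
    LabelError,
    SizeError,
)


class TestShannon:
    @pytest.mark.parametrize("p,expected", [
        ([0.25, 0.25, 0.25, 0.25], np.log(4)),
        ([1, 0, 0], 0.0),
        # direct evaluation: -(0.5 ln 0.5 + 0.3 ln 0.3 + 0.2 ln 0.2)
        ([0.5, 0.3, 0.2], 1.0297),
    ])
    def test_known_values(self, p, expected):
        assert ps.shannon(p) == pytest.approx(expected, abs=1e-4)

    def test_base_two(self):
        assert ps.shannon([0.5, 0.5], base="2") == pytest.approx(1.0)

    def test_renormalizes_counts(self):
        assert ps.shannon([10, 10]) == pytest.approx(np.log(2))

    def test_all_zero_errors(self):
        with pytest.raises(DegenerateSampleError):
            ps.shannon([0, 0, 0])


class TestFaithPD:
    def test_all_leaves_is_total_length(self, balanced_tree):
        total = sum(n.length or 0 for n in balanced_tree.traverse())
        assert ps.faith_pd(["A", "B", "C", "D"], balanced_tree) == pytest.approx(total)

    def test_single_leaf_is_root_path(self, balanced_tree):
        assert ps.faith_pd(["A"], balanced_tree) == pytest.approx(3.0)

    def test_sister_pair_includes_root_edge(self, balanced_tree):
        # two tips (1+1) + their stem (1) + root edge (1)
        assert ps.faith_pd(["A", "B"], balanced_tree) == pytest.approx(4.0)

    def test_matches_skbio_without_root_edge(self):
        tree = skbio.TreeNode.read(["((A:1,B:2):0.5,(C:1.5,D:0.7):2);"])
        from skbio.diversity.alpha import faith_pd as skbio_faith
        for present in (["A", "B"], ["A", "C"], ["A", "B", "D"]):
            counts = [1 if n in present else 0 for n in "ABCD"]
            assert ps.faith_pd(present, tree) == pytest.approx(
                skbio_faith(counts, taxa=list("ABCD"), tree=tree)
            )

    def test_missing_taxon(self, balanced_tree):
        with pytest.raises(LabelError):
            ps.faith_pd(["A", "Z"], balanced_tree)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = ps.FeatureTable(pd.DataFrame({"s1": [3, 1], "s2": [3, 1]},
                                         index=["a", "b"]))
        assert ps.bray_curtis(t)["s1", "s2"] == 0.0

    def test_disjoint_supports_one(self):
        t = ps.FeatureTable(pd.DataFrame({"s1": [3, 0], "s2": [0, 5]},
                                         index=["a", "b"]))
        assert ps.bray_curtis(t)["s1", "s2"] == pytest.approx(1.0)

    def test_hand_value(self):
        t = ps.FeatureTable(pd.DataFrame({"s1": [6, 2], "s2": [2, 2]},
                                         index=["a", "b"]))
        assert ps.bray_curtis(t)["s1", "s2"] == pytest.approx(1 / 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        t = ps.FeatureTable(pd.DataFrame(
            rng.integers(1, 50, size=(5, 4)),
            index=[f"t{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(4)],
        ))
        d = np.asarray(ps.bray_curtis(t).data)
        assert ((d >= 0) & (d <= 1)).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.diag(d).sum() == 0


class TestPcoa:
    def test_equilateral_gives_equal_eigenvalues(self):
        d = skbio.DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        res = ps.pcoa(d)
        ev = np.sort(res.eigvals.to_numpy())[::-1]
        assert ev[0] == pytest.approx(ev[1], rel=1e-8)

    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = skbio.DistanceMatrix(squareform(pdist(pts)), ids=list("abc"))
        res = ps.pcoa(d)
        ev = np.sort(res.eigvals.to_numpy())[::-1]
        assert ev[0] > 1e-8
        assert abs(ev[1]) < 1e-8

    def test_recovers_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        d = skbio.DistanceMatrix(squareform(pdist(pts)),
                                 ids=[f"s{i}" for i in range(6)])
        res = ps.pcoa(d)
        coords = res.samples.to_numpy()
        back = squareform(pdist(coords))
        np.testing.assert_allclose(back, d.data, atol=1e-6)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        mat = squareform(pdist(pts))
        d = skbio.DistanceMatrix(mat, ids=[f"s{i}" for i in range(7)])
        res = ps.pcoa(d)
        n = mat.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ (mat**2) @ j
        assert res.eigvals.sum() == pytest.approx(np.trace(g), abs=1e-8)

    def test_too_small(self):
        d = skbio.DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        with pytest.raises(SizeError):
            ps.pcoa(d)


def _two_group_dm(offset, n_per=4, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, size=(n_per, 2)),
                     rng.normal(offset, 1, size=(n_per, 2))])
    ids = [f"s{i}" for i in range(2 * n_per)]
    groups = ["g1"] * n_per + ["g2"] * n_per
    return skbio.DistanceMatrix(squareform(pdist(pts)), ids=ids), groups


class TestPermanova:
    def test_matches_skbio_pseudo_f(self):
        d, groups = _two_group_dm(offset=2.0, seed=5)
        mine = ps.permanova(d, groups, n_perm=99, seed=1)
        theirs = skbio.stats.distance.permanova(
            d, pd.Series(groups, index=d.ids, name="group"), permutations=0
        )
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_maximal_separation_gives_smallest_p(self):
        # near-identical within-group points, huge between-group offset:
        # no permutation can match the observed F except reproducing the
        # original partition, which is vanishingly unlikely at n = 24
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 1e-6, size=(12, 2)),
                         rng.normal(100, 1e-6, size=(12, 2))])
        d = skbio.DistanceMatrix(squareform(pdist(pts)),
                                 ids=[f"s{i}" for i in range(24)])
        res = ps.permanova(d, ["g1"] * 12 + ["g2"] * 12, n_perm=999, seed=0)
        assert res.p == 1 / (1 + 999)

    def test_r2_is_between_fraction(self):
        d, groups = _two_group_dm(offset=1.0, seed=6)
        res = ps.permanova(d, groups, n_perm=49, seed=2)
        assert 0 <= res.R2 <= 1

    def test_single_group_errors(self):
        d, _ = _two_group_dm(offset=0.0)
        with pytest.raises(DesignError):
            ps.permanova(d, ["g"] * 8)

    def test_seed_reproducible(self):
        d, groups = _two_group_dm(offset=0.5, seed=7)
        a = ps.permanova(d, groups, n_perm=199, seed=11)
        b = ps.permanova(d, groups, n_perm=199, seed=11)
        assert a.p == b.p

    def test_null_p_superuniform(self):
        """Rejection rate at alpha=0.05 under exchangeable labels."""
        rej = 0
        n_sim = 500
        rng = np.random.default_rng(8)
        for i in range(n_sim):
            pts = rng.normal(size=(12, 2))
            d = skbio.DistanceMatrix(squareform(pdist(pts)),
                                     ids=[f"s{k}" for k in range(12)])
            res = ps.permanova(d, ["a"] * 6 + ["b"] * 6, n_perm=99,
                               seed=int(rng.integers(2**31 - 1)))
            rej += res.p <= 0.05
        assert 0.02 <= rej / n_sim <= 0.09


class TestPairwisePermanova:
    def test_two_groups_reduces_to_permanova(self):
        d, groups = _two_group_dm(offset=1.5, seed=9)
        single = ps.permanova(d, groups, n_perm=99, seed=3)
        pair = ps.pairwise_permanova(d, groups, n_perm=99, seed=3)
        assert len(pair) == 1
        assert pair[0].pseudo_F == pytest.approx(single.pseudo_F)

    def test_bh_adjustment_hand_case(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_three_identical_groups_rarely_significant(self):
        rng = np.random.default_rng(10)
        n_sig = 0
        n_sim = 60
        for i in range(n_sim):
            pts = rng.normal(size=(12, 2))
            d = skbio.DistanceMatrix(squareform(pdist(pts)),
                                     ids=[f"s{k}" for k in range(12)])
            res = ps.pairwise_permanova(d, ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                                        n_perm=99,
                                        seed=int(rng.integers(2**31 - 1)))
            if any(r.p_adjusted <= 0.05 for r in res):
                n_sig += 1
        assert n_sig / n_sim <= 0.15


class TestWithinGroupDissimilarity:
    def test_identical_samples_give_zeros(self):
        t = ps.FeatureTable(pd.DataFrame(
            {"s1": [1, 1], "s2": [1, 1], "s3": [2, 0], "s4": [0, 2]},
            index=["a", "b"],
        ))
        d = ps.bray_curtis(t)
        res = ps.within_group_dissimilarity(d, ["g1", "g1", "g2", "g2"])
        np.testing.assert_array_equal(res.values["g1"], [0.0])
        np.testing.assert_array_equal(res.values["g2"], [1.0])

    def test_wilcoxon_exact_hand_case(self):
        from scipy.stats import mannwhitneyu
        _, p = mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided",
                            method="exact")
        assert p == pytest.approx(0.1)

    def test_singleton_group_excluded(self):
        t = ps.FeatureTable(pd.DataFrame(
            {"s1": [1, 0], "s2": [0, 1], "s3": [1, 1]}, index=["a", "b"]
        ))
        d = ps.bray_curtis(t)
        res = ps.within_group_dissimilarity(d, ["g1", "g1", "g2"])
        assert res.excluded == ["g2"]


class TestCompartmentOverlap:
    @staticmethod
    def _table(taxa):
        return ps.FeatureTable(pd.DataFrame(
            {"s": [1] * len(taxa)}, index=list(taxa)
        ))

    def test_set_arithmetic(self):
        out = ps.compartment_overlap({
            "root": self._table("abc"), "leaf": self._table("ad"),
        })
        assert out.loc["leaf", "shared_with_root"] == 1
        assert out.loc["leaf", "frac_shared_with_root"] == pytest.approx(0.5)
        assert out.loc["root", "n_unique"] == 2

    def test_identical_sets(self):
        out = ps.compartment_overlap({
            "root": self._table("ab"), "leaf": self._table("ab"),
        })
        assert out.loc["root", "frac_shared_with_leaf"] == 1.0
        assert out.loc["root", "n_unique"] == 0

    def test_disjoint_sets(self):
        out = ps.compartment_overlap({
            "root": self._table("ab"), "leaf": self._table("cd"),
        })
        assert out.loc["root", "shared_with_leaf"] == 0
        assert out.loc["root", "frac_unique"] == 1.0
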