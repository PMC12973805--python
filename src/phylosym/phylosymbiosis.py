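"""Host-microbiome congruence testing.

Phylosymbiosis is the pattern in which microbial community similarity
parallels host phylogeny.  It is tested here by building a community
dendrogram (UPGMA over Bray-Curtis distances), measuring its topological
distance to the host tree (Robinson-Foulds, matching-cluster, or
clustering-information distance), and comparing the observed distance to
the distribution over uniformly random binary topologies: a host tree
that predicts community structure yields a smaller-than-random distance,
so the p-value counts null trees at least as close as the observed one.

Because the normalized RF score is defined against the random-tree null
mean (nRF = observed / mean of null), values above 1 are possible and
indicate a dendrogram *further* from the host tree than random.

Blomberg's K measures phylogenetic signal in a continuous per-species
trait (e.g. a community summary such as Faith's PD); K ~ 1 under
Brownian motion, K -> 0 when trait variation ignores the phylogeny.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import skbio
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from . import _treeops
from .errors import DegenerateTraitError, InputError, SizeError
from .diversity import DistanceMatrix

METRICS = ("rf", "nrf", "mc", "cid")


@dataclasses.dataclass
class CongruenceResult:
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    normalized: float
    p: float
    n_random_trees: int


@dataclasses.dataclass
class SignalResult:
    K: float
    p: float
    n_perm: int


def upgma_dendrogram(d: DistanceMatrix) -> skbio.TreeNode:
    """Average-linkage (UPGMA) ultrametric dendrogram over a distance
    matrix; leaves carry the matrix labels."""
    if d.shape[0] < 2:
        raise SizeError("need >= 2 labels")
    mat = np.asarray(d.data, dtype=float)
    if np.isnan(mat).any():
        raise InputError("NaN distances")
    linkage = average(squareform(mat, checks=False))
    tree = skbio.TreeNode.from_linkage_matrix(linkage, list(d.ids))
    # from_linkage_matrix stores merge heights; lengths can be negative
    # by float noise on ultrametric input -- clamp.
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def rf_distance(t1: skbio.TreeNode, t2: skbio.TreeNode) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one of
    the two (unrooted) topologies."""
    index = _treeops.check_same_leaves(t1, t2)
    return _treeops.rf_from_splits(
        _treeops.splits(t1, index), _treeops.splits(t2, index)
    )


def matching_cluster_distance(t1: skbio.TreeNode, t2: skbio.TreeNode) -> float:
    """Matching-cluster distance between two rooted trees: minimum-cost
    perfect matching of leaf clusters under symmetric-difference cost."""
    index = _treeops.check_same_leaves(t1, t2)
    return _treeops.matching_cluster_from_clusters(
        _treeops.clusters(t1, index), _treeops.clusters(t2, index)
    )


def cid(t1: skbio.TreeNode, t2: skbio.TreeNode) -> float:
    """Clustering information distance (bits) between two topologies."""
    index = _treeops.check_same_leaves(t1, t2)
    return _treeops.cid_from_splits(
        _treeops.splits(t1, index), _treeops.splits(t2, index), len(index)
    )


def random_tree(labels: list[str], seed: int | None = None) -> skbio.TreeNode:
    """Uniformly random unrooted binary topology over ``labels``,
    rooted arbitrarily at an internal node for Newick output."""
    labels = [str(x) for x in labels]
    if len(labels) < 3:
        raise SizeError("need >= 3 labels")
    if len(set(labels)) != len(labels):
        raise InputError("duplicate labels")
    rng = np.random.default_rng(seed)
    topo = _treeops.RandomTopology(len(labels), rng)
    return skbio.TreeNode.read([topo.to_newick(labels)])


def phylosymbiosis_test(
    host: skbio.TreeNode,
    dendro: skbio.TreeNode,
    metric: str = "rf",
    n_random: int = 100_000,
    seed: int | None = None,
) -> CongruenceResult:
    """Random-tree null test of host/dendrogram topological congruence.

    ``p = (1 + #{null distance <= observed}) / (1 + n_random)``: small
    distances mean congruence, so the lower tail is the signal tail.
    Branch lengths are ignored (all three metrics are topology-only).
    The ``nrf`` metric runs the RF test; its score is the
    ``normalized`` field (observed RF / null mean), which can exceed 1.
    """
    metric = metric.lower()
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}; choose from {METRICS}")
    index = _treeops.check_same_leaves(host, dendro)
    n = len(index)
    host_splits = _treeops.splits(host, index)
    host_clusters = _treeops.clusters(host, index)

    def dist_vs_host(d_splits, d_clusters):
        if metric in ("rf", "nrf"):
            return _treeops.rf_from_splits(host_splits, d_splits)
        if metric == "mc":
            return _treeops.matching_cluster_from_clusters(host_clusters, d_clusters)
        return _treeops.cid_from_splits(host_splits, d_splits, n)

    observed = dist_vs_host(
        _treeops.splits(dendro, index), _treeops.clusters(dendro, index)
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    need_clusters = metric == "mc"
    for i in range(n_random):
        topo = _treeops.RandomTopology(n, rng)
        null[i] = dist_vs_host(
            None if need_clusters else topo.splits(),
            topo.clusters() if need_clusters else None,
        )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_random > 1 else 0.0
    p = float((1 + int((null <= observed).sum())) / (1 + n_random))
    normalized = float(observed / null_mean) if null_mean > 0 else float("nan")
    return CongruenceResult(metric, float(observed), null_mean, null_sd,
                            normalized, p, n_random)


# ---------------------------------------------------------------------------
# phylogenetic signal


def tree_vcv(tree: skbio.TreeNode, labels: list[str]) -> np.ndarray:
    """Brownian-motion variance-covariance matrix of tip values: shared
    root-to-MRCA path length per tip pair."""
    tips = {t.name: t for t in tree.tips()}
    missing = set(labels) - set(tips)
    if missing:
        raise InputError(f"labels absent from tree: {sorted(missing)}")
    depth: dict[int, float] = {}
    for node in tree.preorder():
        base = depth[id(node.parent)] if node.parent is not None else 0.0
        depth[id(node)] = base + (node.length or 0.0)
    root_dist = np.array([depth[id(tips[l])] for l in labels])
    dm = tree.tip_tip_distances(endpoints=list(labels))
    d = np.asarray(dm.filter(labels).data)
    c = (root_dist[:, None] + root_dist[None, :] - d) / 2.0
    np.fill_diagonal(c, root_dist)
    return c


def _k_ratio(y: np.ndarray, vinv: np.ndarray, ones: np.ndarray) -> float:
    """MSE0/MSE for a trait vector given the inverse VCV."""
    n = len(y)
    a = float(ones @ vinv @ y) / float(ones @ vinv @ ones)
    resid = y - a
    mse = float(resid @ vinv @ resid) / (n - 1)
    mse0 = float(np.sum((y - y.mean()) ** 2)) / (n - 1)
    return mse0 / mse


def blombergs_k(
    tree: skbio.TreeNode,
    trait: "pd.Series | dict[str, float]",
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with significance by tip-label permutation.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected-under-BM with the
    phylogenetically corrected mean, where the Brownian expectation is
    (tr(V) - n / sum(V^-1)) / (n - 1).  The permutation p-value is the
    fraction of shuffled traits with a ratio at least as large as
    observed, with the (1 + count) / (1 + n_perm) estimator.
    """
    if isinstance(trait, dict):
        trait = pd.Series(trait)
    labels = [t.name for t in tree.tips()]
    missing = set(labels) - set(trait.index.astype(str))
    if missing:
        raise InputError(f"trait missing for leaves: {sorted(missing)}")
    y = trait.loc[labels].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise DegenerateTraitError("constant trait")
    v = tree_vcv(tree, labels)
    if (np.diag(v) <= 0).any():
        raise InputError("tree has zero root-to-tip distances")
    vinv = np.linalg.inv(v)
    n = len(y)
    ones = np.ones(n)
    expected = (np.trace(v) - n / float(ones @ vinv @ ones)) / (n - 1)
    obs_ratio = _k_ratio(y, vinv, ones)
    k = obs_ratio / expected
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _k_ratio(rng.permutation(y), vinv, ones) >= obs_ratio:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return SignalResult(float(k), float(p), n_perm)
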