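"""Low-level topology machinery shared by the congruence metrics.

Bipartitions (splits) and rooted clusters are encoded as integer
bitmasks over a fixed leaf index, which keeps Robinson-Foulds,
matching-cluster, and clustering-information computations fast enough
to drive random-tree null distributions with thousands of draws.

Random topologies are sampled uniformly over unrooted binary trees by
sequential edge attachment: leaf i+1 is attached to a uniformly chosen
edge of the i-leaf tree, which yields each labeled topology by exactly
one construction path.
"""

from __future__ import annotations

import numpy as np
import skbio
from scipy.optimize import linear_sum_assignment

from .errors import LabelError, SizeError


def leaf_index(tree: skbio.TreeNode) -> dict[str, int]:
    names = sorted(t.name for t in tree.tips())
    return {name: i for i, name in enumerate(names)}


def check_same_leaves(t1: skbio.TreeNode, t2: skbio.TreeNode) -> dict[str, int]:
    n1 = {t.name for t in t1.tips()}
    n2 = {t.name for t in t2.tips()}
    if n1 != n2:
        raise LabelError(
            f"leaf sets differ: only-in-first={sorted(n1 - n2)}, "
            f"only-in-second={sorted(n2 - n1)}"
        )
    return {name: i for i, name in enumerate(sorted(n1))}


def _node_masks(tree: skbio.TreeNode, index: dict[str, int]) -> dict[int, int]:
    """Postorder descendant-leaf bitmask per node (keyed by id(node))."""
    masks: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip():
            if node.name not in index:
                raise LabelError(f"leaf {node.name!r} not in index")
            masks[id(node)] = 1 << index[node.name]
        else:
            m = 0
            for child in node.children:
                m |= masks[id(child)]
            masks[id(node)] = m
    return masks


def splits(tree: skbio.TreeNode, index: dict[str, int]) -> frozenset[int]:
    """Non-trivial bipartitions of the unrooted topology, canonicalized
    so each split is represented by the side not containing leaf 0."""
    n = len(index)
    full = (1 << n) - 1
    masks = _node_masks(tree, index)
    out = set()
    for node in tree.postorder():
        if node.is_tip() or node.parent is None:
            continue
        m = masks[id(node)]
        if m & 1:
            m = full ^ m
        if 2 <= bin(m).count("1") <= n - 2:
            out.add(m)
    return frozenset(out)


def clusters(tree: skbio.TreeNode, index: dict[str, int]) -> list[int]:
    """Non-trivial rooted clusters (internal-node leaf sets, root excluded)."""
    n = len(index)
    masks = _node_masks(tree, index)
    out = []
    for node in tree.postorder():
        if node.is_tip() or node.parent is None:
            continue
        m = masks[id(node)]
        if 2 <= bin(m).count("1") <= n - 1:
            out.append(m)
    return out


def rf_from_splits(s1: frozenset[int], s2: frozenset[int]) -> int:
    return len(s1 ^ s2)


def matching_cluster_from_clusters(c1: list[int], c2: list[int]) -> float:
    """Minimum-cost perfect matching between cluster sets; cost is the
    symmetric-difference size, with empty clusters as padding."""
    k = max(len(c1), len(c2))
    if k == 0:
        return 0.0
    a = list(c1) + [0] * (k - len(c1))
    b = list(c2) + [0] * (k - len(c2))
    cost = np.empty((k, k))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            cost[i, j] = bin(x ^ y).count("1")
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def split_entropy(mask: int, n: int) -> float:
    """Entropy (bits) of the two-block partition induced by a split."""
    a = bin(mask).count("1")
    b = n - a
    pa, pb = a / n, b / n
    return float(-(pa * np.log2(pa) + pb * np.log2(pb)))


def _pair_mci(m1: int, m2: int, n: int) -> float:
    """Mutual clustering information (bits) between two splits."""
    full = (1 << n) - 1
    total = 0.0
    for x, px in ((m1, bin(m1).count("1")), (full ^ m1, n - bin(m1).count("1"))):
        for y, py in ((m2, bin(m2).count("1")), (full ^ m2, n - bin(m2).count("1"))):
            c = bin(x & y).count("1")
            if c:
                total += (c / n) * np.log2(c * n / (px * py))
    return float(total)


def cid_from_splits(s1: frozenset[int], s2: frozenset[int], n: int) -> float:
    """Clustering information distance (bits): summed split entropies
    minus twice the optimal-matching mutual clustering information."""
    l1, l2 = sorted(s1), sorted(s2)
    h1 = sum(split_entropy(m, n) for m in l1)
    h2 = sum(split_entropy(m, n) for m in l2)
    if not l1 or not l2:
        return h1 + h2
    k = max(len(l1), len(l2))
    gain = np.zeros((k, k))
    for i, a in enumerate(l1):
        for j, b in enumerate(l2):
            gain[i, j] = _pair_mci(a, b, n)
    rows, cols = linear_sum_assignment(-gain)
    return float(h1 + h2 - 2 * gain[rows, cols].sum())


# ---------------------------------------------------------------------------
# random unrooted binary topologies


class RandomTopology:
    """Uniform random unrooted binary topology on leaves 0..n-1.

    Stores an adjacency list; splits/clusters are derived on demand.
    Leaf k is node k; internal nodes are numbered from n upward.
    """

    def __init__(self, n: int, rng: np.random.Generator):
        if n < 3:
            raise SizeError("need >= 3 leaves")
        self.n = n
        adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
        edges: list[tuple[int, int]] = []

        def add_edge(u, v):
            adj[u].append(v)
            adj[v].append(u)
            edges.append((u, v))

        add_edge(n, 0)
        add_edge(n, 1)
        add_edge(n, 2)
        next_internal = n + 1
        for leaf in range(3, n):
            ei = int(rng.integers(len(edges)))
            u, v = edges[ei]
            w = next_internal
            next_internal += 1
            adj[u].remove(v)
            adj[v].remove(u)
            edges[ei] = (u, w)
            adj[u].append(w)
            adj[w].append(u)
            add_edge(w, v)
            add_edge(w, leaf)
        self.adj = adj

    def _masks_below(self, root: int) -> dict[int, int]:
        """Descendant-leaf mask per node when rooted at ``root``
        (iterative postorder)."""
        masks: dict[int, int] = {}
        stack = [(root, -1, False)]
        while stack:
            node, parent, done = stack.pop()
            if done:
                m = 1 << node if node < self.n else 0
                for nb in self.adj[node]:
                    if nb != parent:
                        m |= masks[nb]
                masks[node] = m
            else:
                stack.append((node, parent, True))
                for nb in self.adj[node]:
                    if nb != parent:
                        stack.append((nb, node, False))
        return masks

    def splits(self) -> frozenset[int]:
        n, full = self.n, (1 << self.n) - 1
        masks = self._masks_below(n)
        out = set()
        for node in range(n + 1, 2 * n - 2):
            m = masks[node]
            if m & 1:
                m = full ^ m
            if 2 <= bin(m).count("1") <= n - 2:
                out.add(m)
        return frozenset(out)

    def clusters(self) -> list[int]:
        """Clusters after rooting arbitrarily at internal node n."""
        n = self.n
        masks = self._masks_below(n)
        out = []
        for node in range(n + 1, 2 * n - 2):
            m = masks[node]
            if 2 <= bin(m).count("1") <= n - 1:
                out.append(m)
        return out

    def to_newick(self, labels: list[str]) -> str:
        def rec(node: int, parent: int) -> str:
            if node < self.n:
                return labels[node]
            parts = [rec(nb, node) for nb in self.adj[node] if nb != parent]
            return "(" + ",".join(parts) + ")"

        return rec(self.n, -1) + ";"
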