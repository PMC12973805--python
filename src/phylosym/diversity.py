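"""Alpha/beta diversity, ordination, PERMANOVA, and overlap accounting.

Beta diversity is Bray-Curtis throughout, matching the distance the rest
of the pipeline is built on (dendrograms, ordination, within-group
dissimilarity).  PERMANOVA is computed from the partition of squared
distances so that R^2 = SS_between / SS_total is available alongside the
pseudo-F; p-values use the (1 + count) / (1 + n_perm) permutation
estimator.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateSampleError,
    DesignError,
    InputError,
    LabelError,
    SizeError,
)
from .tables_io import FeatureTable

DistanceMatrix = skbio.DistanceMatrix


@dataclasses.dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    group_pair: tuple[str, str] | None = None
    p_adjusted: float | None = None


def shannon(p: Sequence[float], base: str = "e") -> float:
    """Shannon entropy H = -sum p_i log p_i of a (renormalized) profile."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise InputError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero abundance vector")
    p = p[p > 0] / total
    h = -np.sum(p * np.log(p))
    if base == "2":
        h /= np.log(2)
    elif base != "e":
        raise InputError(f"unknown log base: {base!r}")
    return float(h)


def faith_pd(present_taxa: Sequence[str], tree: skbio.TreeNode) -> float:
    """Faith's phylogenetic diversity.

    Total branch length of the minimal subtree connecting the present
    taxa to the root, including the root's own edge when one is present
    (the classic Faith definition; some tools stop at the subtree MRCA,
    so the convention matters for comparisons).
    """
    tips = {t.name: t for t in tree.tips()}
    missing = set(map(str, present_taxa)) - set(tips)
    if missing:
        raise LabelError(f"taxa absent from tree: {sorted(missing)}")
    if not present_taxa:
        return 0.0
    counted = set()
    total = 0.0
    for name in set(map(str, present_taxa)):
        node = tips[name]
        while node is not None and id(node) not in counted:
            counted.add(id(node))
            if node.length is not None:
                total += node.length
            node = node.parent
    return float(total)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if table.n_samples < 2:
        raise SizeError("need >= 2 samples")
    totals = table.sample_totals()
    if (totals <= 0).any():
        raise DegenerateSampleError(
            f"zero-total samples: {list(totals[totals <= 0].index)}"
        )
    d = pdist(table.values.T, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


def pcoa(d: DistanceMatrix):
    """Principal coordinate analysis (Gower double-centering).

    Returns scikit-bio's ``OrdinationResults`` (axes, eigenvalues,
    proportions explained).
    """
    if d.shape[0] < 3:
        raise SizeError("PCoA needs >= 3 samples")
    return skbio.stats.ordination.pcoa(d, method="eigh", number_of_dimensions=0)


def _permanova_stat(sq: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from a squared-distance matrix and group codes."""
    n = sq.shape[0]
    ss_total = sq[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    f = (ss_between / df_between) / (ss_within / df_within) if ss_within > 0 else np.inf
    return f, ss_between / ss_total


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free permutation of
    sample labels."""
    labels = _aligned_labels(d, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise DesignError("PERMANOVA needs >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise DesignError(
            f"groups with < 2 members: {list(uniq[counts < 2])}"
        )
    sq = np.asarray(d.data) ** 2
    f_obs, r2 = _permanova_stat(sq, codes, len(uniq))
    rng = np.random.default_rng(seed)
    count = 0
    perm_codes = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_codes)
        f_perm, _ = _permanova_stat(sq, perm_codes, len(uniq))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def pairwise_permanova(
    d: DistanceMatrix,
    groups: Sequence[str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    adjust: str = "BH",
) -> list[PermanovaResult]:
    """PERMANOVA for every pair of groups, with optional Benjamini-
    Hochberg adjustment across pairs."""
    if adjust not in ("BH", "none"):
        raise InputError(f"unknown adjustment: {adjust!r}")
    labels = _aligned_labels(d, groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DesignError("need >= 2 groups")
    ids = np.asarray(d.ids)
    results = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(uniq, 2):
        mask = (labels == a) | (labels == b)
        sub = d.filter(ids[mask])
        res = permanova(sub, labels[mask], n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
        res.group_pair = (str(a), str(b))
        results.append(res)
    if adjust == "BH" and results:
        adj = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results


def _aligned_labels(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = set(d.ids) - set(groups.index.astype(str))
        if missing:
            raise LabelError(f"samples without group labels: {sorted(missing)}")
        return groups.loc[list(d.ids)].astype(str).to_numpy()
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != d.shape[0]:
        raise InputError("group vector length does not match distance matrix")
    return groups


@dataclasses.dataclass
class WithinGroupDissimilarity:
    values: dict[str, np.ndarray]
    tests: pd.DataFrame
    excluded: list[str]


def within_group_dissimilarity(
    d: DistanceMatrix,
    groups: Sequence[str] | pd.Series,
) -> WithinGroupDissimilarity:
    """All within-group pairwise distances per group, plus two-sided
    Wilcoxon rank-sum tests between every pair of groups.

    Groups with fewer than two members have no within-group pairs and
    are excluded (recorded in ``excluded``).  The rank-sum test uses
    exact enumeration for small groups and the tie-corrected normal
    approximation otherwise.
    """
    labels = _aligned_labels(d, groups)
    mat = np.asarray(d.data)
    values: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            excluded.append(str(g))
            continue
        sub = mat[np.ix_(idx, idx)]
        values[str(g)] = sub[np.triu_indices(len(idx), 1)]
    rows = []
    for a, b in itertools.combinations(sorted(values), 2):
        va, vb = values[a], values[b]
        method = "exact" if (len(va) <= 20 and len(vb) <= 20) else "asymptotic"
        stat, p = mannwhitneyu(va, vb, alternative="two-sided", method=method)
        rows.append({"group_a": a, "group_b": b, "U": float(stat), "p": float(p)})
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])
    return WithinGroupDissimilarity(values, tests, excluded)


def compartment_overlap(tables: Mapping[str, FeatureTable]) -> pd.DataFrame:
    """Shared/unique ASV accounting between compartments.

    For each compartment the output reports its ASV count, the count and
    fraction of its ASVs present in each other compartment, and the
    count/fraction unique to it (present in no other compartment).
    """
    if len(tables) < 2:
        raise SizeError("need >= 2 compartments")
    presence = {}
    for name, t in tables.items():
        taxa = {tid for tid, s in t.data.sum(axis=1).items() if s > 0}
        if not taxa:
            raise DegenerateSampleError(f"compartment {name!r} has no present taxa")
        presence[name] = taxa
    rows = []
    for name, taxa in presence.items():
        row = {"compartment": name, "n_asvs": len(taxa)}
        others = set()
        for other, otaxa in presence.items():
            if other == name:
                continue
            shared = taxa & otaxa
            row[f"shared_with_{other}"] = len(shared)
            row[f"frac_shared_with_{other}"] = len(shared) / len(taxa)
            others |= otaxa
        uniq = taxa - others
        row["n_unique"] = len(uniq)
        row["frac_unique"] = len(uniq) / len(taxa)
        rows.append(row)
    return pd.DataFrame(rows).set_index("compartment")


def chao1(counts: Sequence[float]) -> float:
    """Standard Chao1 richness estimator (simple utility)."""
    counts = np.rint(np.asarray(counts, dtype=float)).astype(int)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def observed_features(counts: Sequence[float]) -> int:
    return int((np.asarray(counts, dtype=float) > 0).sum())
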