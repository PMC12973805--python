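"""Phylogenetic community structure: MPD/SES-MPD, betaMNTD/betaNTI, and
an alignment-free k-mer TF-IDF analogue of MPD.

SES-MPD standardizes the abundance-weighted mean pairwise phylogenetic
distance within each sample against a null obtained by shuffling taxon
labels on the phylogenetic distance matrix ("taxa labels" null): values
below -2 indicate phylogenetic clustering, above +2 overdispersion.

betaNTI applies the same standardization to between-sample mean
nearest-taxon distances; |betaNTI| > 2 is conventionally read as
deterministic (selection-driven) turnover, |betaNTI| < 2 as
stochastic.

The k-mer route sidesteps a taxon phylogeny entirely: sequences are
decomposed into overlapping k-mers (k = 16 by default), TF-IDF
weighted, and the pairwise cosine distance between taxon profiles
replaces the cophenetic distance in the weighted MPD formula.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy import sparse

from .errors import InputError, LabelError, SizeError
from .tables_io import FeatureTable, relative_abundance


@dataclasses.dataclass
class SesResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_null: int

    @property
    def classification(self) -> str:
        if self.ses < -2:
            return "clustered"
        if self.ses > 2:
            return "overdispersed"
        return "neutral"


def mpd(
    abundances: Sequence[float],
    d: np.ndarray,
    weighted: bool = True,
) -> float:
    """Mean pairwise distance among present taxa.

    Weighted: sum_{i!=j} d_ij p_i p_j / sum_{i!=j} p_i p_j; unweighted:
    plain mean over distinct present-taxon pairs.
    """
    p = np.asarray(abundances, dtype=float)
    d = np.asarray(d, dtype=float)
    present = np.flatnonzero(p > 0)
    if len(present) < 2:
        raise SizeError("MPD undefined for < 2 present taxa")
    sub = d[np.ix_(present, present)]
    if weighted:
        w = p[present]
        wmat = np.outer(w, w)
        np.fill_diagonal(wmat, 0.0)
        return float((sub * wmat).sum() / wmat.sum())
    iu = np.triu_indices(len(present), 1)
    return float(sub[iu].mean())


def _taxon_distances(table: FeatureTable, tree: skbio.TreeNode) -> np.ndarray:
    names = {t.name for t in tree.tips()}
    missing = set(table.taxon_ids) - names
    if missing:
        raise LabelError(f"taxa absent from tree: {sorted(missing)}")
    dm = tree.tip_tip_distances(endpoints=table.taxon_ids)
    return np.asarray(dm.filter(table.taxon_ids).data)


def ses_mpd(
    table: FeatureTable,
    tree: skbio.TreeNode,
    n_null: int = 999,
    null_model: str = "taxa_labels",
    seed: int | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-sample SES of abundance-weighted MPD under taxon-label
    shuffling.  Returns a DataFrame with observed, null moments, ses,
    and the clustered/overdispersed/neutral call."""
    if null_model != "taxa_labels":
        raise InputError(f"unsupported null model: {null_model!r}")
    d = _taxon_distances(table, tree)
    rel = relative_abundance(table).values
    rng = np.random.default_rng(seed)
    ntaxa = d.shape[0]
    obs = np.array([mpd(rel[:, j], d, weighted) for j in range(rel.shape[1])])
    nulls = np.empty((n_null, rel.shape[1]))
    for b in range(n_null):
        perm = rng.permutation(ntaxa)
        dperm = d[np.ix_(perm, perm)]
        for j in range(rel.shape[1]):
            nulls[b, j] = mpd(rel[:, j], dperm, weighted)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    ses = np.where(sd > 0, (obs - mean) / sd, 0.0)
    cls = np.where(ses < -2, "clustered", np.where(ses > 2, "overdispersed", "neutral"))
    return pd.DataFrame(
        {
            "observed": obs,
            "null_mean": mean,
            "null_sd": sd,
            "ses": ses,
            "classification": cls,
            "n_null": n_null,
        },
        index=table.sample_ids,
    )


def _bmntd_matrix(rel: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Abundance-weighted between-sample mean nearest-taxon distances.

    For each ordered sample pair (A, B), each present taxon in A
    contributes its distance to the nearest present taxon of B,
    weighted by its relative abundance; the two directions are
    averaged.
    """
    n_samples = rel.shape[1]
    present = [np.flatnonzero(rel[:, j] > 0) for j in range(n_samples)]
    out = np.zeros((n_samples, n_samples))
    for a in range(n_samples):
        ia = present[a]
        wa = rel[ia, a]
        for b in range(a + 1, n_samples):
            ib = present[b]
            wb = rel[ib, b]
            dab = d[np.ix_(ia, ib)]
            forward = float(wa @ dab.min(axis=1))
            backward = float(wb @ dab.min(axis=0))
            out[a, b] = out[b, a] = 0.5 * (forward + backward)
    return out


def bnti(
    table: FeatureTable,
    tree: skbio.TreeNode,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise betaNTI matrix (samples x samples DataFrame).

    betaNTI_ij = (betaMNTD_obs - null mean) / null sd with the null from
    shuffling taxon labels on the distance matrix.  The diagonal is 0
    (a community's nearest-taxon distance to itself is 0).
    """
    if table.n_samples < 2:
        raise SizeError("need >= 2 samples")
    if (table.values.sum(axis=0) <= 0).any():
        raise InputError("samples with no present taxa")
    d = _taxon_distances(table, tree)
    rel = relative_abundance(table).values
    obs = _bmntd_matrix(rel, d)
    rng = np.random.default_rng(seed)
    ntaxa = d.shape[0]
    nulls = np.empty((n_null,) + obs.shape)
    for b in range(n_null):
        perm = rng.permutation(ntaxa)
        nulls[b] = _bmntd_matrix(rel, d[np.ix_(perm, perm)])
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, 0.0)
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def stochasticity_fraction(bnti_values: Sequence[float]) -> tuple[float, float]:
    """(stochastic, deterministic) fractions of a betaNTI collection,
    with |betaNTI| >= 2 counted as deterministic."""
    v = np.asarray(list(bnti_values), dtype=float)
    if v.size == 0:
        raise InputError("empty betaNTI list")
    det = float((np.abs(v) >= 2).mean())
    return 1.0 - det, det


# ---------------------------------------------------------------------------
# k-mer TF-IDF profiles


@dataclasses.dataclass
class KmerProfileSet:
    """Sparse TF-IDF k-mer profiles, one row per taxon (L2-normalized)."""

    taxon_ids: list[str]
    matrix: sparse.csr_matrix
    k: int
    n_features: int

    def cosine_distances(self, taxa: Sequence[str]) -> np.ndarray:
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise LabelError(f"taxa without k-mer profiles: {missing}")
        rows = self.matrix[[index[t] for t in taxa]]
        sim = np.asarray((rows @ rows.T).todense())
        d = 1.0 - np.clip(sim, -1.0, 1.0)
        np.fill_diagonal(d, 0.0)
        return d


def kmerize(
    seqs: Mapping[str, str],
    k: int = 16,
    max_features: int = 5000,
    tfidf: bool = True,
) -> KmerProfileSet:
    """Overlapping k-mer counting with TF-IDF weighting.

    Ambiguous positions (anything outside ACGT) are dropped before
    windowing.  The feature space is truncated to the ``max_features``
    k-mers with the highest document frequency; TF-IDF uses the
    smooth-idf convention tf * (ln((1 + n) / (1 + df)) + 1) followed by
    per-profile L2 normalization.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    taxon_ids = list(seqs)
    counts: list[dict[str, int]] = []
    for tid in taxon_ids:
        s = "".join(c for c in str(seqs[tid]).upper() if c in "ACGT")
        if len(s) < k:
            raise InputError(f"sequence {tid!r} shorter than k={k} after cleaning")
        cnt: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            cnt[kmer] = cnt.get(kmer, 0) + 1
        counts.append(cnt)
    df_count: dict[str, int] = {}
    for cnt in counts:
        for kmer in cnt:
            df_count[kmer] = df_count.get(kmer, 0) + 1
    # highest document frequency first; lexicographic tie-break for determinism
    vocab = sorted(df_count, key=lambda w: (-df_count[w], w))[:max_features]
    col = {w: i for i, w in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for r, cnt in enumerate(counts):
        for kmer, c in cnt.items():
            j = col.get(kmer)
            if j is not None:
                rows.append(r)
                cols.append(j)
                vals.append(float(c))
    mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(taxon_ids), len(vocab))
    )
    if tfidf:
        n = len(taxon_ids)
        dfv = np.array([df_count[w] for w in vocab], dtype=float)
        idf = np.log((1 + n) / (1 + dfv)) + 1.0
        mat = mat.multiply(idf[None, :]).tocsr()
    norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    mat = sparse.diags(1.0 / norms) @ mat
    return KmerProfileSet(taxon_ids, mat.tocsr(), k, len(vocab))


def kmer_mpd(
    table: FeatureTable,
    profiles: KmerProfileSet,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample abundance-weighted MPD with cosine distance between
    k-mer profiles standing in for phylogenetic distance."""
    d = profiles.cosine_distances(table.taxon_ids)
    rel = relative_abundance(table).values
    out = {}
    for j, sid in enumerate(table.sample_ids):
        out[sid] = mpd(rel[:, j], d, weighted)
    return pd.Series(out, name="kmer_mpd")
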