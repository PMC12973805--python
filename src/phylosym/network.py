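"""Compositional correlation networks and keystone-taxon detection.

Relative-abundance data are compositional: naive correlations between
proportions are biased negative.  SparCC estimates correlations between
the underlying (unobserved) absolute abundances from log-ratio
variances, under the assumption that the true correlation network is
sparse; strongly correlated pairs are iteratively excluded from the
basis-variance estimate to protect that assumption.  Significance is a
pseudo p-value from permuted data (each taxon's counts shuffled across
samples independently).

Thresholded networks feed topological-role analysis: modules by greedy
modularity maximization, then the within-module degree z-score (Zi) and
among-module participation coefficient (Pi) classify nodes as module
hubs (Zi >= 2.5, Pi < 0.62), connectors (Zi < 2.5, Pi >= 0.62), network
hubs (both), or peripherals.  Connectors and hubs are the usual
keystone candidates.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InputError, SizeError
from .tables_io import FeatureTable

TRAIT_NODE_KINGDOM = "trait"

# threshold presets mirroring common reporting conventions
PROFILES = {
    "igraph": {"r_threshold": 0.6, "alpha": 0.05},
    "sparcc": {"r_threshold": 0.4, "alpha": 0.05},
}


@dataclasses.dataclass
class CorrelationNetwork:
    graph: nx.Graph  # nodes carry 'kingdom'; edges carry r, p, sign
    r_threshold: float
    alpha: float
    absolute: bool

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "r": d["r"], "p": d["p"], "sign": d["sign"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p", "sign"])


@dataclasses.dataclass
class NodeRole:
    node: str
    module_id: int
    Zi: float
    Pi: float
    role: str


def _basis_correlations(log_frac: np.ndarray, exclusion_iterations: int,
                        exclusion_threshold: float) -> np.ndarray:
    """One SparCC basis-correlation estimate from log fractions
    (taxa x samples), with iterative strong-pair exclusion."""
    d = log_frac.shape[0]
    cov = np.cov(log_frac)
    var = np.diag(cov).copy()
    t = var[:, None] + var[None, :] - 2 * cov  # var(log(x_i/x_j))
    excluded: set[tuple[int, int]] = set()
    excluded_count = np.zeros(d, dtype=int)

    def solve() -> np.ndarray:
        m = np.full((d, d), 1.0)
        np.fill_diagonal(m, d - 1.0)
        b = t.sum(axis=1).astype(float)
        for i, j in excluded:
            m[i, i] -= 1
            m[j, j] -= 1
            m[i, j] -= 1
            m[j, i] -= 1
            b[i] -= t[i, j]
            b[j] -= t[i, j]
        w = np.linalg.solve(m, b)
        w = np.maximum(w, 1e-12)
        with np.errstate(invalid="ignore"):
            r = (w[:, None] + w[None, :] - t) / (2 * np.sqrt(np.outer(w, w)))
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    r = solve()
    for _ in range(exclusion_iterations):
        masked = np.abs(r).copy()
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # never exclude a taxon from too many pairs, or the system degenerates
        if excluded_count[i] >= d - 3 or excluded_count[j] >= d - 3:
            break
        excluded.add((min(i, j), max(i, j)))
        excluded_count[i] += 1
        excluded_count[j] += 1
        r = solve()
    return r


def _sparcc_point(counts: np.ndarray, rng: np.random.Generator,
                  n_iterations: int, exclusion_iterations: int,
                  exclusion_threshold: float) -> np.ndarray:
    """Average basis correlations over Dirichlet-resampled fractions."""
    estimates = []
    for _ in range(n_iterations):
        frac = np.empty_like(counts, dtype=float)
        for j in range(counts.shape[1]):
            frac[:, j] = rng.dirichlet(counts[:, j] + 1.0)
        estimates.append(
            _basis_correlations(np.log(frac), exclusion_iterations,
                                exclusion_threshold)
        )
    return np.mean(estimates, axis=0)


def sparcc(
    table: FeatureTable,
    n_iterations: int = 20,
    exclusion_iterations: int = 10,
    exclusion_threshold: float = 0.1,
    n_bootstrap: int = 100,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SparCC correlation matrix and permutation pseudo p-values.

    Returns (r, p) DataFrames over the table's taxa.  Zero-total taxa
    are excluded with a warning; pseudo-p uses the
    (1 + count) / (1 + n_bootstrap) estimator on |r| of datasets with
    each taxon's counts independently shuffled across samples.
    """
    totals = table.data.sum(axis=1)
    zero = list(totals[totals <= 0].index)
    if zero:
        warnings.warn(f"excluding zero-total taxa: {zero}", stacklevel=2)
        table = table.filter_taxa([t for t in table.taxon_ids if t not in zero])
    if table.n_taxa < 3:
        raise SizeError("SparCC needs >= 3 taxa")
    if table.n_samples < 20:
        warnings.warn(
            f"SparCC on {table.n_samples} samples; >= 20 recommended",
            stacklevel=2,
        )
    counts = table.values
    rng = np.random.default_rng(seed)
    r_obs = _sparcc_point(counts, rng, n_iterations, exclusion_iterations,
                          exclusion_threshold)
    exceed = np.zeros_like(r_obs)
    for _ in range(n_bootstrap):
        perm = np.empty_like(counts)
        for i in range(counts.shape[0]):
            perm[i] = rng.permutation(counts[i])
        # permuted data carry no real correlation structure; a single
        # Dirichlet draw per dataset is enough for the null magnitude
        r_perm = _sparcc_point(perm, rng, 1, exclusion_iterations,
                               exclusion_threshold)
        exceed += np.abs(r_perm) >= np.abs(r_obs)
    p = (1 + exceed) / (1 + n_bootstrap)
    np.fill_diagonal(p, 0.0)
    ids = table.taxon_ids
    return (pd.DataFrame(r_obs, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
    absolute: bool = True,
    trait: "pd.Series | None" = None,
    trait_name: str = "trait",
    abundances: "FeatureTable | None" = None,
    kingdoms: Mapping[str, str] | None = None,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a graph.

    An edge is kept when |r| > r_threshold (or r > r_threshold with
    ``absolute=False``) and p < alpha.  When a per-sample ``trait`` and
    the source ``abundances`` table are supplied, the trait becomes a
    node whose edges to taxa are Pearson correlations filtered by the
    same rule.  ``kingdoms`` tags nodes (e.g. bacteria/fungi) for the
    association summary.
    """
    if list(r.index) != list(r.columns) or r.shape != p.shape or \
            list(r.index) != list(p.index):
        raise InputError("r and p matrices must be aligned and square")
    kingdoms = dict(kingdoms or {})
    g = nx.Graph()
    ids = list(r.index)
    for node in ids:
        g.add_node(node, kingdom=kingdoms.get(node, "unknown"))
    rv = r.to_numpy()
    pv = p.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            val = rv[i, j]
            strength = abs(val) if absolute else val
            if strength > r_threshold and pv[i, j] < alpha:
                g.add_edge(ids[i], ids[j], r=float(val), p=float(pv[i, j]),
                           sign="positive" if val > 0 else "negative")
    if trait is not None:
        if abundances is None:
            raise InputError("trait edges need the abundance table")
        g.add_node(trait_name, kingdom=TRAIT_NODE_KINGDOM)
        trait = trait.dropna()
        samples = [s for s in abundances.sample_ids if s in trait.index]
        y = trait.loc[samples].to_numpy(dtype=float)
        sub = abundances.filter_samples(samples)
        for tid in ids:
            x = sub.data.loc[tid].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            rr, pp = pearsonr(x, y)
            strength = abs(rr) if absolute else rr
            if strength > r_threshold and pp < alpha:
                g.add_edge(tid, trait_name, r=float(rr), p=float(pp),
                           sign="positive" if rr > 0 else "negative")
    return CorrelationNetwork(g, r_threshold, alpha, absolute)


def node_roles(net: CorrelationNetwork, seed: int | None = None) -> list[NodeRole]:
    """Zi/Pi topological roles from greedy-modularity modules.

    Modules are detected on the unsigned graph; isolated nodes get
    their own module with Zi = 0, Pi = 0 (peripheral).  Within a module
    whose degree spread is zero, Zi is defined as 0.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise InputError("network has no edges")
    connected = [n for n in g.nodes if g.degree(n) > 0]
    communities = nx.community.greedy_modularity_communities(g.subgraph(connected))
    # deterministic module ids: order by smallest member label
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    module_of = {}
    for mid, members in enumerate(communities):
        for n in members:
            module_of[n] = mid
    next_mid = len(communities)
    for n in g.nodes:
        if n not in module_of:
            module_of[n] = next_mid
            next_mid += 1
    # within-module degree stats
    kin: dict[str, int] = {}
    for n in g.nodes:
        kin[n] = sum(1 for nb in g.neighbors(n) if module_of[nb] == module_of[n])
    stats: dict[int, tuple[float, float]] = {}
    for mid in set(module_of.values()):
        vals = np.array([kin[n] for n in g.nodes if module_of[n] == mid], float)
        stats[mid] = (float(vals.mean()), float(vals.std(ddof=0)))
    roles = []
    for n in sorted(g.nodes, key=str):
        k = g.degree(n)
        mean, sd = stats[module_of[n]]
        zi = (kin[n] - mean) / sd if sd > 0 else 0.0
        if k > 0:
            shares: dict[int, int] = {}
            for nb in g.neighbors(n):
                shares[module_of[nb]] = shares.get(module_of[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in shares.values())
        else:
            pi = 0.0
        if zi >= 2.5 and pi >= 0.62:
            role = "network_hub"
        elif zi >= 2.5:
            role = "module_hub"
        elif pi >= 0.62:
            role = "connector"
        else:
            role = "peripheral"
        roles.append(NodeRole(str(n), module_of[n], float(zi), float(pi), role))
    return roles


@dataclasses.dataclass
class TraitAssociationSummary:
    n_linked_nodes: int
    per_kingdom: dict[str, int]
    positive_fraction: float | None  # None when the trait has no edges


def trait_association_summary(
    net: CorrelationNetwork,
    trait_name: str = "trait",
) -> TraitAssociationSummary:
    """Count and characterize the taxa directly linked to the trait node."""
    g = net.graph
    if trait_name not in g.nodes:
        raise InputError(f"no trait node {trait_name!r} in network")
    neighbors = list(g.neighbors(trait_name))
    per_kingdom: dict[str, int] = {}
    positive = 0
    for nb in neighbors:
        kd = g.nodes[nb].get("kingdom", "unknown")
        per_kingdom[kd] = per_kingdom.get(kd, 0) + 1
        if g.edges[trait_name, nb]["sign"] == "positive":
            positive += 1
    frac = positive / len(neighbors) if neighbors else None
    return TraitAssociationSummary(len(neighbors), per_kingdom, frac)
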