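"""Synthetic-data generators with the statistical structure the
pipeline assumes.

The generators emulate a multi-species common-garden study: a set of
host species related by an ultrametric phylogeny, several replicate
root samples per species, and a shared pool of microbial taxa whose
per-species expected abundances carry a tunable amount of host-
phylogenetic signal.  The phylosymbiosis strength ``s`` interpolates
between communities that ignore the host tree (s = 0) and communities
whose between-species differences are pure Brownian motion on it
(s = 1).  Default sizes follow the study design the package targets:
18 host species with 4 replicate root samples each, 300 taxa,
sequencing depth 100,000 reads per sample.

A separate Hubbell-style forward simulator produces neutral local
communities with a known immigration probability for exercising the
Sloan neutral-model fit, and a linear trait generator plants known
driver taxa for the trait-prediction analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import skbio

from .errors import ConfigError, LabelError, SizeError
from .phylosymbiosis import tree_vcv
from .tables_io import FeatureTable, SampleMetadata

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SynthConfig:
    """Study-design parameters for the phylosymbiotic community generator.

    ``phylosymbiosis_strength`` (s) is the fraction of between-species
    log-abundance variance explained by Brownian motion on the host
    tree; ``brownian_sigma`` scales that between-species variance and
    ``noise_sigma`` the per-replicate log-abundance noise.
    ``dm_concentration`` controls Dirichlet-multinomial overdispersion
    of replicate counts (None = plain multinomial).
    """

    n_species: int = 18
    n_replicates_per_species: int = 4
    n_taxa: int = 300
    sequencing_depth: int = 100_000
    phylosymbiosis_strength: float = 0.8
    brownian_sigma: float = 1.0
    noise_sigma: float = 0.3
    dm_concentration: float | None = 500.0
    neutral_N: int = 1000
    neutral_m: float = 0.1
    trait_noise_sd: float = 0.1
    seq_length: int = 250
    taxon_tree_height: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.n_species < 3 or self.n_replicates_per_species < 1 \
                or self.n_taxa < 2 or self.sequencing_depth < 1:
            raise ConfigError("all counts must be positive (>= 3 species)")
        if not 0 <= self.phylosymbiosis_strength <= 1:
            raise ConfigError("phylosymbiosis_strength must lie in [0, 1]")
        if self.brownian_sigma < 0 or self.noise_sigma < 0:
            raise ConfigError("sigmas must be non-negative")


def simulate_host_tree(
    n_species: int,
    seed: int | None = None,
    rate: float = 1.0,
    prefix: str = "sp",
) -> skbio.TreeNode:
    """Ultrametric pure-birth (Yule) tree with ``n_species`` leaves.

    Lineages split at constant rate; the present is set one extra
    waiting time after the last split so every tip has positive
    terminal branch length.  Reproducible under ``seed``.
    """
    if n_species < 3:
        raise SizeError("need >= 3 species")
    rng = np.random.default_rng(seed)
    root = skbio.TreeNode()
    c1, c2 = skbio.TreeNode(), skbio.TreeNode()
    root.extend([c1, c2])
    active = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (rate * len(active)))
        node, birth = active.pop(int(rng.integers(len(active))))
        node.length = t - birth
        a, b = skbio.TreeNode(), skbio.TreeNode()
        node.extend([a, b])
        active.extend([(a, t), (b, t)])
    present = t + rng.exponential(1.0 / (rate * n_species))
    width = len(str(n_species))
    for i, (node, birth) in enumerate(active):
        node.length = present - birth
        node.name = f"{prefix}{i + 1:0{width}d}"
    root.length = None
    return root


def simulate_phylosymbiotic_communities(
    host: skbio.TreeNode,
    cfg: SynthConfig,
) -> tuple[FeatureTable, SampleMetadata, skbio.TreeNode, dict[str, str]]:
    """Replicated per-species count tables with tunable phylosymbiosis.

    Per taxon, species-level latent log abundances are drawn from
    N(0, sigma_b^2 [s C + (1 - s) I]) where C is the host tree's
    Brownian covariance scaled to unit depth: at s = 1 between-species
    structure is pure phylogeny, at s = 0 pure species-specific noise.
    Replicates add iid N(0, noise_sigma^2) log-noise and are sampled
    Dirichlet-multinomial at the sequencing depth.  A Yule taxon tree
    is simulated alongside and sequences are evolved on it under
    Jukes-Cantor, so k-mer distances correlate with taxon-tree
    distances.

    Returns (counts, metadata, taxon_tree, sequences).
    """
    rng = np.random.default_rng(cfg.seed)
    species = [t.name for t in host.tips()]
    if len(species) != cfg.n_species:
        raise ConfigError(
            f"host tree has {len(species)} leaves, config says {cfg.n_species}"
        )
    c = tree_vcv(host, species)
    c = c / np.diag(c).max()
    s = cfg.phylosymbiosis_strength
    cov = cfg.brownian_sigma**2 * (s * c + (1 - s) * np.eye(len(species)))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(species)))
    width = len(str(cfg.n_taxa))
    taxa = [f"t{i + 1:0{width}d}" for i in range(cfg.n_taxa)]
    base = rng.normal(0.0, 1.5, size=cfg.n_taxa)
    species_effects = (chol @ rng.standard_normal((len(species), cfg.n_taxa))).T
    counts = {}
    meta_rows = []
    ploidy = rng.choice(["diploid", "allotetraploid"], size=len(species),
                        p=[0.7, 0.3])
    life = rng.choice(["annual", "perennial"], size=len(species))
    genome = [f"{chr(ord('A') + i % 7)}{chr(ord('A') + i % 7)}"
              for i in range(len(species))]
    div_class = _divergence_classes(species)
    for si, sp in enumerate(species):
        for r in range(cfg.n_replicates_per_species):
            sid = f"{sp}_r{r + 1}"
            log_ab = base + species_effects[:, si] \
                + rng.normal(0.0, cfg.noise_sigma, size=cfg.n_taxa)
            p = np.exp(log_ab - log_ab.max())
            p /= p.sum()
            if cfg.dm_concentration is not None:
                g = rng.gamma(np.maximum(p * cfg.dm_concentration, 1e-9))
                p = g / g.sum()
            counts[sid] = rng.multinomial(cfg.sequencing_depth, p)
            meta_rows.append({
                "sample_id": sid,
                "species": sp,
                "divergence_class": div_class[sp],
                "ploidy": ploidy[si],
                "life_cycle": life[si],
                "compartment": "root",
                "genome_type": genome[si],
            })
    table = FeatureTable(pd.DataFrame(counts, index=taxa), provenance="synthetic")
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    taxon_tree = simulate_host_tree(
        cfg.n_taxa, seed=int(rng.integers(2**31 - 1)), prefix="t"
    )
    _scale_tree_height(taxon_tree, cfg.taxon_tree_height)
    seqs = evolve_sequences(
        taxon_tree, cfg.seq_length, seed=int(rng.integers(2**31 - 1))
    )
    return table, metadata, taxon_tree, seqs


def _divergence_classes(species: list[str]) -> dict[str, str]:
    """Assign early/medium/late by thirds of the tree's tip order, a
    clade-respecting proxy for the real study's divergence phases."""
    n = len(species)
    out = {}
    for i, sp in enumerate(species):
        if i < n / 3:
            out[sp] = "early"
        elif i < 2 * n / 3:
            out[sp] = "medium"
        else:
            out[sp] = "late"
    return out


def _scale_tree_height(tree: skbio.TreeNode, height: float) -> None:
    depths = {id(tree): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depths[id(node)] = depths[id(node.parent)] + (node.length or 0.0)
    depth = max(depths[id(t)] for t in tree.tips())
    if depth <= 0:
        return
    for node in tree.traverse():
        if node.length is not None:
            node.length *= height / depth


def evolve_sequences(
    tree: skbio.TreeNode,
    length: int = 250,
    seed: int | None = None,
) -> dict[str, str]:
    """Evolve nucleotide sequences down a tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site; per site the
    probability of observing a different base after a branch of length
    t is (3/4)(1 - exp(-4t/3)).
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(4, size=length)
    seqs: dict[str, str] = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in getattr(node, "children", []):
            t = child.length or 0.0
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            mutate = rng.random(length) < p_diff
            new = seq.copy()
            if mutate.any():
                shifts = rng.integers(1, 4, size=int(mutate.sum()))
                new[mutate] = (new[mutate] + shifts) % 4
            if child.is_tip():
                seqs[child.name] = "".join(_BASES[new])
            else:
                stack.append((child, new))
    return seqs


def simulate_neutral_metacommunity(
    N: int,
    m: float,
    source: np.ndarray,
    n_samples: int,
    seed: int | None = None,
    burn_in_factor: int = 10,
) -> FeatureTable:
    """Hubbell-style neutral local communities under a common source pool.

    Each sample holds N individuals evolved by single-individual
    death/replacement events: with probability ``m`` the replacement
    immigrates from the source distribution, otherwise it copies a
    random local individual.  The stationary law of this process is
    Dirichlet-multinomial with concentration I = m (N - 1) / (1 - m),
    and each community is initialized exactly at stationarity by a
    Hoppe-urn construction (individual k is an immigrant with
    probability I / (I + k), else copies a random earlier individual)
    before running ``burn_in_factor * N`` further events.
    """
    if not 0 < m <= 1:
        raise ConfigError("m must lie in (0, 1]")
    if N < 100:
        raise ConfigError("N must be >= 100")
    source = np.asarray(source, dtype=float)
    if (source < 0).any() or source.sum() <= 0:
        raise ConfigError("source must be a non-negative abundance vector")
    source = source / source.sum()
    rng = np.random.default_rng(seed)
    cum = np.cumsum(source)
    n_taxa = len(source)
    width = len(str(n_taxa))
    taxa = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    n_events = burn_in_factor * N
    conc = m * (N - 1) / (1 - m) if m < 1 else np.inf
    data = np.empty((n_taxa, n_samples), dtype=int)
    for j in range(n_samples):
        if np.isinf(conc):
            community = np.searchsorted(cum, rng.random(N))
        else:
            community = np.empty(N, dtype=np.int64)
            immigrant = rng.random(N) < conc / (conc + np.arange(N))
            draws = np.searchsorted(cum, rng.random(N))
            community[0] = draws[0]
            for k in range(1, N):
                community[k] = (
                    draws[k] if immigrant[k] else community[rng.integers(k)]
                )
        deaths = rng.integers(N, size=n_events)
        immigrates = rng.random(n_events) < m
        imm_taxa = np.searchsorted(cum, rng.random(n_events))
        parents = rng.integers(N, size=n_events)
        for i in range(n_events):
            community[deaths[i]] = (
                imm_taxa[i] if immigrates[i] else community[parents[i]]
            )
        data[:, j] = np.bincount(community, minlength=n_taxa)
    cols = [f"s{j + 1:03d}" for j in range(n_samples)]
    return FeatureTable(pd.DataFrame(data, index=taxa, columns=cols),
                        provenance="synthetic:neutral")


def choose_trait_drivers(
    table: FeatureTable,
    candidates: "set[str] | list[str]",
    k: int = 5,
    max_mutual_correlation: float = 0.6,
) -> list[str]:
    """Pick ``k`` candidate taxa suitable as trait drivers.

    A planted trait signal is only recoverable by feature-importance
    analysis if its drivers are identifiable: a driver whose abundance
    profile is nearly a linear combination of other taxa can be proxied
    away.  Candidates are therefore ranked by uniqueness (residual
    variance after ridge-regressing each one on all other taxa) and
    greedily accepted subject to a cap on mutual correlation.
    """
    from sklearn.linear_model import Ridge

    rel = table.data / table.data.sum(axis=0)
    x = rel.to_numpy().T
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd
    ids = list(rel.index)
    cand = sorted(set(candidates))
    if len(cand) < k:
        raise ConfigError(f"need >= {k} candidate taxa, got {len(cand)}")
    uniqueness = {}
    for t in cand:
        i = ids.index(t)
        others = np.delete(xz, i, axis=1)
        fit = Ridge(alpha=10.0).fit(others, xz[:, i])
        uniqueness[t] = float((xz[:, i] - fit.predict(others)).var())
    order = sorted(cand, key=lambda t: -uniqueness[t])
    corr = np.corrcoef(rel.loc[cand].to_numpy())
    idx = {t: j for j, t in enumerate(cand)}
    picked = [order[0]]
    for t in order[1:]:
        if len(picked) == k:
            break
        if all(abs(corr[idx[t], idx[p]]) < max_mutual_correlation
               for p in picked):
            picked.append(t)
    for t in order:  # relax the correlation cap if it was too strict
        if len(picked) == k:
            break
        if t not in picked:
            picked.append(t)
    return picked


def calibrate_trait_effects(
    table: FeatureTable,
    driver_taxa: list[str],
) -> np.ndarray:
    """Effect sizes giving each driver an equal variance contribution.

    Magnitudes are 1/sd of each driver's relative abundance; signs are
    assigned greedily so that correlated drivers reinforce rather than
    cancel (the variance of the running signed sum is maximized), which
    keeps every driver's marginal contribution to the trait non-trivial.
    """
    rel = (table.data / table.data.sum(axis=0)).loc[list(driver_taxa)]
    x = rel.to_numpy()
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ConfigError("driver with constant relative abundance")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    signs = [1.0]
    running = z[0].copy()
    for i in range(1, z.shape[0]):
        if np.var(running + z[i]) >= np.var(running - z[i]):
            signs.append(1.0)
            running = running + z[i]
        else:
            signs.append(-1.0)
            running = running - z[i]
    return np.array(signs) / sd


def simulate_trait(
    table: FeatureTable,
    driver_taxa: list[str],
    effects: np.ndarray,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> pd.Series:
    """Per-sample trait linearly driven by designated taxa.

    trait_j = sum_d effect_d * (relative abundance of driver d in j)
    + N(0, noise_sd^2).
    """
    missing = set(driver_taxa) - set(table.taxon_ids)
    if missing:
        raise LabelError(f"unknown driver taxa: {sorted(missing)}")
    effects = np.asarray(effects, dtype=float)
    if len(effects) != len(driver_taxa):
        raise ConfigError("effects must align with driver_taxa")
    rng = np.random.default_rng(seed)
    rel = table.data / table.data.sum(axis=0)
    drivers = rel.loc[list(driver_taxa)].to_numpy()
    trait = effects @ drivers + rng.normal(0.0, noise_sd, size=table.n_samples)
    return pd.Series(trait, index=table.sample_ids, name="trait")
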