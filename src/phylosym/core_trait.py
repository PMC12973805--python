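"""Core-microbiome identification, niche breadth, taxonomic collapsing,
and trait prediction from community composition.

A taxon is "core" when it is simultaneously abundant (top decile of
mean relative abundance across samples) and prevalent (present in more
than half of samples).  Levins' niche breadth B summarizes how evenly a
taxon spreads over samples (B = 1 single-habitat specialist, B = number
of samples for a perfectly even generalist).  Trait prediction uses
random-forest regression with out-of-fold predictions; feature
importance is permutation importance measured on held-out folds, which
is model-agnostic and unbiased toward high-cardinality features.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import DegenerateTraitError, InputError, ParseError
from .tables_io import FeatureTable, relative_abundance

TAXONOMIC_LEVELS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclasses.dataclass
class CoreSet:
    core_taxa: set[str]
    abundance_quantile: float
    prevalence_threshold: float


@dataclasses.dataclass
class TraitModelResult:
    MAE: float
    predictions: pd.Series
    importance: pd.Series
    cv_scheme: str


def identify_core(
    table: FeatureTable,
    abundance_quantile: float = 0.90,
    prevalence: float = 0.50,
) -> CoreSet:
    """Taxa in the top (1 - quantile) fraction of mean relative
    abundance AND present in more than ``prevalence`` of samples."""
    if table.n_taxa == 0 or table.n_samples == 0:
        raise InputError("empty table")
    if not (0 <= abundance_quantile < 1) or not (0 <= prevalence < 1):
        raise InputError("thresholds must lie in [0, 1)")
    rel = relative_abundance(table)
    mean_ra = rel.data.mean(axis=1)
    n_top = max(1, int(np.ceil(table.n_taxa * (1 - abundance_quantile))))
    abundant = set(mean_ra.sort_values(ascending=False, kind="stable").index[:n_top])
    prev = (table.data > 0).mean(axis=1)
    prevalent = set(prev.index[prev > prevalence])
    return CoreSet(abundant & prevalent, abundance_quantile, prevalence)


def niche_breadth(table: FeatureTable) -> pd.Series:
    """Levins' niche breadth per taxon: B_i = 1 / sum_j q_ij^2 where
    q_ij is taxon i's abundance share in sample j.  All-zero taxa are
    excluded with a warning."""
    x = table.values
    totals = x.sum(axis=1)
    zero = [t for t, s in zip(table.taxon_ids, totals) if s <= 0]
    if zero:
        warnings.warn(f"excluding all-zero taxa: {zero}", stacklevel=2)
    keep = totals > 0
    q = x[keep] / totals[keep, None]
    b = 1.0 / np.sum(q**2, axis=1)
    return pd.Series(b, index=[t for t, k in zip(table.taxon_ids, keep) if k],
                     name="niche_breadth")


def community_niche_breadth(table: FeatureTable, taxa: Sequence[str]) -> float:
    """Bcom: mean niche breadth over a taxon set (e.g. the core)."""
    b = niche_breadth(table)
    taxa = [t for t in taxa if t in b.index]
    if not taxa:
        raise InputError("no taxa with defined niche breadth")
    return float(b.loc[taxa].mean())


def _lineage_at(lineage: str, level: str) -> str | None:
    parts = [p.strip() for p in str(lineage).split(";")]
    idx = TAXONOMIC_LEVELS.index(level)
    if idx >= len(parts):
        return None
    token = parts[idx]
    if "__" in token:
        prefix, _, name = token.partition("__")
        if prefix.lower() != level[0]:
            raise ParseError(
                f"lineage {lineage!r}: rank prefix {token!r} does not match "
                f"requested level {level!r}"
            )
        token = name
    return token or None


def collapse_taxonomy(
    table: FeatureTable,
    taxonomy: Mapping[str, str] | pd.Series,
    level: str = "genus",
) -> FeatureTable:
    """Sum rows within identical labels at a taxonomic level.

    Lineages are semicolon-separated, optionally Greengenes-style
    (``k__...; p__...``).  Taxa unassigned at the level (or missing a
    lineage) pool into ``unclassified``.  ``level='asv'`` is the
    identity.
    """
    if level == "asv":
        return table
    if level not in TAXONOMIC_LEVELS:
        raise InputError(f"unknown level {level!r}")
    if isinstance(taxonomy, pd.Series):
        taxonomy = taxonomy.to_dict()
    labels = []
    for tid in table.taxon_ids:
        lineage = taxonomy.get(tid)
        name = _lineage_at(lineage, level) if lineage is not None else None
        labels.append(name if name else "unclassified")
    collapsed = table.data.groupby(labels).sum()
    return FeatureTable(collapsed, provenance=f"collapsed:{level}")


def predict_trait(
    table: FeatureTable,
    trait: "pd.Series | Mapping[str, float]",
    cv_folds: int = 10,
    n_trees: int = 500,
    seed: int | None = None,
    n_importance_repeats: int = 5,
) -> TraitModelResult:
    """Random-forest regression of a per-sample trait on community
    composition with out-of-fold evaluation.

    Predictions for every sample come from the fold that held it out;
    MAE is the mean absolute error of those predictions.  Feature
    importance is permutation importance evaluated on held-out data,
    pooled across folds: a feature's column is permuted globally and
    each fold's model re-predicts its own held-out samples, so one
    importance score draws on every sample rather than averaging many
    small-fold estimates.
    """
    if not isinstance(trait, pd.Series):
        trait = pd.Series(dict(trait))
    trait = trait.dropna()
    samples = [s for s in table.sample_ids if s in trait.index]
    if len(samples) < cv_folds:
        raise InputError(
            f"{len(samples)} samples with trait values < {cv_folds} folds"
        )
    y = trait.loc[samples].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise DegenerateTraitError("constant trait")
    rel = relative_abundance(table.filter_samples(samples))
    X = rel.values.T  # samples x taxa
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=cv_folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    folds = list(kf.split(X))
    preds = np.empty(len(samples))
    models = []
    for train, test in folds:
        model = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        model.fit(X[train], y[train])
        preds[test] = model.predict(X[test])
        models.append(model)
    base_mse = float(np.mean((preds - y) ** 2))
    importance = np.zeros(X.shape[1])
    for _ in range(n_importance_repeats):
        perm = rng.permutation(len(y))
        for f in range(X.shape[1]):
            xp = X.copy()
            xp[:, f] = X[perm, f]
            pp = np.empty(len(y))
            for (train, test), model in zip(folds, models):
                pp[test] = model.predict(xp[test])
            importance[f] += np.mean((pp - y) ** 2) - base_mse
    importance /= n_importance_repeats
    mae = float(np.mean(np.abs(preds - y)))
    return TraitModelResult(
        MAE=mae,
        predictions=pd.Series(preds, index=samples, name="predicted"),
        importance=pd.Series(importance, index=rel.taxon_ids,
                             name="importance"),
        cv_scheme=f"{cv_folds}-fold out-of-fold, {n_trees} trees, pooled "
                  f"held-out permutation importance "
                  f"({n_importance_repeats} repeats)",
    )


def core_importance_contrast(
    result: TraitModelResult,
    core: CoreSet,
) -> tuple[float, float, float]:
    """(mean core importance, mean non-core importance, two-sided
    rank-sum p) comparing predictor importance between core and
    non-core taxa."""
    imp = result.importance
    core_taxa = [t for t in imp.index if t in core.core_taxa]
    other = [t for t in imp.index if t not in core.core_taxa]
    if not core_taxa or not other:
        raise InputError("both core and non-core groups must be non-empty")
    a = imp.loc[core_taxa].to_numpy()
    b = imp.loc[other].to_numpy()
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.mean()), float(b.mean()), 1.0
    _, p = mannwhitneyu(a, b, alternative="two-sided")
    return float(a.mean()), float(b.mean()), float(p)
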