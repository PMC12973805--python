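"""Sloan neutral community model fit and assembly-process reporting.

The Sloan model predicts a taxon's occurrence frequency across local
communities from its mean relative abundance in the metacommunity,
given one free parameter Nm (community size x immigration
probability): frequent immigration keeps locally rare taxa present,
while drift under weak immigration removes them.  The predicted
occurrence frequency for a taxon with mean relative abundance p is

    f_hat(p) = 1 - I_d(Nm * p, Nm * (1 - p))

where I is the regularized incomplete beta function and d the
detection limit (1/N with N the mean reads per sample, the Sloan
convention).  Nm is fitted by least squares on the frequency scale,
and taxa are classified against a 95% Wilson binomial band around the
prediction: taxa above the band are detected more often than neutral
expectation (e.g. host-selected), taxa below less often (e.g. actively
filtered or dispersal-limited).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc
from statsmodels.stats.proportion import proportion_confint

from .errors import FitError, InputError
from .phylostructure import stochasticity_fraction
from .tables_io import FeatureTable

NM_MAX = 1e7


@dataclasses.dataclass
class NcmFit:
    Nm: float
    m: float
    N: float
    R2: float
    detection_limit: float
    taxa: pd.DataFrame  # per-taxon: mean_abundance, frequency, predicted, class


def predicted_frequency(p: np.ndarray, Nm: float, detection_limit: float) -> np.ndarray:
    """Sloan occurrence-frequency prediction for mean abundances ``p``."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return 1.0 - betainc(Nm * p, Nm * (1.0 - p), detection_limit)


def fit_ncm(table: FeatureTable, seed: int | None = None) -> NcmFit:
    """Fit the neutral model to a count table.

    Warns below the recommended scale (10 samples / 20 taxa) and when
    every taxon is present everywhere (frequency carries no
    information); raises :class:`FitError` if the 1-D least-squares
    profile has no interior optimum.
    """
    x = table.values
    n_taxa, n_samples = x.shape
    if n_samples < 10 or n_taxa < 20:
        warnings.warn(
            f"NCM fit on {n_samples} samples x {n_taxa} taxa is below the "
            "recommended scale (10 samples, 20 taxa)",
            stacklevel=2,
        )
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        raise InputError("zero-total samples")
    rel = x / totals
    p_mean = rel.mean(axis=1)
    keep = p_mean > 0
    p_mean = p_mean[keep]
    freq = (x[keep] > 0).mean(axis=1)
    taxa_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    n_big = float(totals.mean())
    d = 1.0 / n_big
    if np.allclose(freq, 1.0):
        warnings.warn("all taxa present in every sample; Nm is weakly identified",
                      stacklevel=2)

    def sse(log_nm: float) -> float:
        fhat = predicted_frequency(p_mean, np.exp(log_nm), d)
        return float(np.sum((freq - fhat) ** 2))

    res = minimize_scalar(sse, bounds=(np.log(1e-3), np.log(NM_MAX)),
                          method="bounded", options={"xatol": 1e-8})
    if not res.success:
        raise FitError("NCM least squares did not converge", last_iterate=res)
    nm = float(np.exp(res.x))
    fhat = predicted_frequency(p_mean, nm, d)
    sst = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lo, hi = proportion_confint(np.round(fhat * n_samples), n_samples, alpha=0.05,
                                method="wilson")
    cls = np.where(freq > hi, "above", np.where(freq < lo, "below", "within"))
    taxa = pd.DataFrame(
        {
            "mean_abundance": p_mean,
            "frequency": freq,
            "predicted": fhat,
            "lower": lo,
            "upper": hi,
            "class": cls,
        },
        index=taxa_ids,
    )
    return NcmFit(Nm=nm, m=nm / n_big, N=n_big, R2=float(r2),
                  detection_limit=d, taxa=taxa)


def assembly_report(
    bnti_matrix: pd.DataFrame,
    groups: "pd.Series | Sequence[str] | None" = None,
) -> pd.DataFrame:
    """Stochastic/deterministic fractions from a betaNTI matrix.

    Rows: one per group (within-group sample pairs only) plus an
    ``all`` row over every distinct pair.  Groups with fewer than two
    samples contribute no pairs and are excluded with a warning.
    """
    mat = bnti_matrix.to_numpy()
    ids = list(bnti_matrix.index)
    iu = np.triu_indices(len(ids), 1)
    all_vals = mat[iu]
    rows = []
    if groups is not None:
        if not isinstance(groups, pd.Series):
            groups = pd.Series(list(groups), index=ids)
        missing = set(ids) - set(groups.index.astype(str))
        if missing:
            raise InputError(f"samples without group labels: {sorted(missing)}")
        labels = groups.loc[ids].astype(str).to_numpy()
        for g in np.unique(labels):
            idx = np.flatnonzero(labels == g)
            if len(idx) < 2:
                warnings.warn(f"group {g!r} has < 2 samples; excluded", stacklevel=2)
                continue
            sub = mat[np.ix_(idx, idx)]
            vals = sub[np.triu_indices(len(idx), 1)]
            s, det = stochasticity_fraction(vals)
            rows.append({"group": g, "n_pairs": len(vals),
                         "stochastic": s, "deterministic": det})
    s, det = stochasticity_fraction(all_vals)
    rows.append({"group": "all", "n_pairs": len(all_vals),
                 "stochastic": s, "deterministic": det})
    return pd.DataFrame(rows).set_index("group")
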