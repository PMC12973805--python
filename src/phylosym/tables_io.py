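"""Feature tables, sample metadata, and the readers/writers around them.

The central container is :class:`FeatureTable`, a thin validated wrapper
around a taxa x samples :class:`pandas.DataFrame` of non-negative
abundances.  Tables arrive as QIIME-style TSV (first column the taxon
key, ``#OTU ID`` accepted with or without the leading ``#``) or BIOM 2.1
HDF5; trees are Newick via scikit-bio; sequences are FASTA.

Normalization follows the common amplicon convention of bringing every
sample to a fixed library size (100,000 reads by default).  Total-sum
scaling with largest-remainder integer rounding is the deterministic
default; rarefaction (subsampling without replacement) is available
behind ``mode="rarefy"``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
import skbio

from .errors import (
    DegenerateSampleError,
    DepthError,
    IdentifierError,
    InputError,
    MetadataError,
    ParseError,
)

DIVERGENCE_CLASSES = ("early", "medium", "late")
PLOIDIES = ("diploid", "allotetraploid")
LIFE_CYCLES = ("annual", "perennial")
COMPARTMENTS = ("root", "shoot", "leaf")


@dataclasses.dataclass
class FeatureTable:
    """Taxa x samples abundance matrix with aligned identifiers.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are taxa, columns are samples.  Entries must be >= 0 and
        identifiers unique on both axes.
    provenance : str, optional
        Free-text note on how the table was derived (e.g. whether an
        aggregated table holds summed counts or mean relative
        abundances).
    """

    data: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self):
        df = self.data
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        df = df.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample ids: {dups}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric entries in feature table: {exc}")
        if np.isnan(values).any():
            raise ParseError("NaN entries in feature table")
        if (values < 0).any():
            raise ParseError("negative entries in feature table")
        self.data = df

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def filter_samples(self, keep: Iterable[str]) -> "FeatureTable":
        keep = [str(s) for s in keep]
        missing = set(keep) - set(self.sample_ids)
        if missing:
            raise IdentifierError(f"unknown samples: {sorted(missing)}")
        return FeatureTable(self.data[keep], provenance=self.provenance)

    def filter_taxa(self, keep: Iterable[str]) -> "FeatureTable":
        keep = [str(t) for t in keep]
        missing = set(keep) - set(self.taxon_ids)
        if missing:
            raise IdentifierError(f"unknown taxa: {sorted(missing)}")
        return FeatureTable(self.data.loc[keep], provenance=self.provenance)


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample host factors and traits, indexed by ``sample_id``.

    Categorical factors (``divergence_class``, ``ploidy``, ``life_cycle``,
    ``compartment``) are validated against their allowed levels when
    present; ``grain_weight``, when present, must be non-negative.
    """

    data: pd.DataFrame

    _ENUMS = {
        "divergence_class": DIVERGENCE_CLASSES,
        "ploidy": PLOIDIES,
        "life_cycle": LIFE_CYCLES,
        "compartment": COMPARTMENTS,
    }

    def __post_init__(self):
        df = self.data.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample ids in metadata: {dups}")
        for col, levels in self._ENUMS.items():
            if col in df.columns:
                bad = set(df[col].dropna().astype(str)) - set(levels)
                if bad:
                    raise ParseError(
                        f"invalid {col} levels {sorted(bad)}; allowed: {levels}"
                    )
        if "grain_weight" in df.columns:
            gw = pd.to_numeric(df["grain_weight"], errors="coerce")
            if (gw.dropna() < 0).any():
                raise ParseError("grain_weight must be non-negative")
            df["grain_weight"] = gw
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def factor(self, name: str, samples: Iterable[str] | None = None) -> pd.Series:
        """Return one metadata column, optionally aligned to ``samples``."""
        if name not in self.data.columns:
            raise MetadataError(f"unknown metadata factor: {name!r}")
        col = self.data[name]
        if samples is not None:
            samples = [str(s) for s in samples]
            missing = set(samples) - set(self.data.index)
            if missing:
                raise MetadataError(f"samples missing from metadata: {sorted(missing)}")
            col = col.loc[samples]
        return col

    def require_cover(self, table: FeatureTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise MetadataError(f"samples missing from metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a taxa x samples feature table from TSV or BIOM 2.1 HDF5."""
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise InputError(f"unknown feature-table format: {format!r}")


def _read_tsv(path: Path) -> FeatureTable:
    try:
        with open(path) as fh:
            first = fh.readline()
            # QIIME exports often start with a '# Constructed from biom file' line
            skip = 1 if first.startswith("# ") and "\t" not in first.strip() else 0
            if skip:
                first = fh.readline()
        # check the raw header: pandas would silently rename duplicates
        header = first.rstrip("\n").split("\t")
        if len(set(header[1:])) != len(header[1:]):
            raise IdentifierError(f"duplicate sample columns in {path}")
        df = pd.read_csv(path, sep="\t", skiprows=skip, header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty feature-table file: {path}")
    if df.shape[1] < 2:
        raise ParseError(f"feature table needs a taxon column and >=1 sample: {path}")
    key = df.columns[0]
    df = df.set_index(key)
    df.index.name = key.lstrip("#").strip() or "OTU ID"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric entry in {path}: {exc}")
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise InputError(f"unknown feature-table format: {format!r}")


def _read_biom(path: Path) -> FeatureTable:
    # Minimal BIOM 2.1 (HDF5, CSR in observation group) support.
    with h5py.File(path, "r") as fh:
        taxa = [t.decode() if isinstance(t, bytes) else str(t) for t in fh["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr), shape=(len(taxa), len(samples)))
    return FeatureTable(pd.DataFrame(mat.toarray(), index=taxa, columns=samples))


def _write_biom(table: FeatureTable, path: Path) -> None:
    from scipy.sparse import csr_matrix

    mat = csr_matrix(table.values)
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-version"] = [2, 1]
        fh.attrs["generated-by"] = "phylosym"
        fh.create_dataset("observation/ids", data=[t.encode() for t in table.taxon_ids])
        fh.create_dataset("sample/ids", data=[s.encode() for s in table.sample_ids])
        fh.create_dataset("observation/matrix/data", data=mat.data.astype(float))
        fh.create_dataset("observation/matrix/indices", data=mat.indices)
        fh.create_dataset("observation/matrix/indptr", data=mat.indptr)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata from a TSV with a ``sample_id`` header column."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty metadata file: {path}")
    if "sample_id" not in df.columns:
        raise ParseError(f"metadata must have a 'sample_id' column: {path}")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted Newick tree; validates leaf-label uniqueness."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise IdentifierError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence dict."""
    seqs: dict[str, str] = {}
    for seq in skbio.io.read(str(path), format="fasta", constructor=skbio.DNA, lowercase=True):
        sid = seq.metadata["id"]
        if sid in seqs:
            raise IdentifierError(f"duplicate sequence id: {sid}")
        seqs[sid] = str(seq).upper()
    if not seqs:
        raise ParseError(f"no sequences in {path}")
    return seqs


def write_sequences(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs.items():
            fh.write(f">{sid}\n{s}\n")


# ---------------------------------------------------------------------------
# normalization and aggregation


def normalize_table(
    table: FeatureTable,
    depth: int = 100_000,
    mode: str = "scale",
    seed: int | None = None,
) -> FeatureTable:
    """Bring every sample to a fixed total count.

    ``scale`` multiplies each column to sum to ``depth`` and rounds by
    largest remainder, so column sums are exactly ``depth`` and the
    within-sample rank order of taxa is preserved.  ``rarefy``
    subsamples reads without replacement, reproducibly under ``seed``.
    """
    if depth <= 0:
        raise InputError("depth must be positive")
    totals = table.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(f"zero-total samples: {list(zero.index)}")
    x = table.values
    if mode == "scale":
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            out[:, j] = _largest_remainder(x[:, j] * depth / totals.iloc[j], depth)
    elif mode == "rarefy":
        short = totals[totals < depth]
        if len(short):
            raise DepthError(
                f"samples below rarefaction depth {depth}: {list(short.index)}"
            )
        rng = np.random.default_rng(seed)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            counts = np.rint(x[:, j]).astype(np.int64)
            out[:, j] = rng.multivariate_hypergeometric(counts, depth)
    else:
        raise InputError(f"unknown normalization mode: {mode!r}")
    return FeatureTable(
        pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids),
        provenance=f"normalized:{mode}:{depth}",
    )


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals summing to ``total`` to integers with the
    same sum, assigning leftover units to the largest fractional parts."""
    floors = np.floor(target)
    remainder = int(round(total - floors.sum()))
    if remainder > 0:
        frac = target - floors
        # stable tie-break: larger fraction first, then lower index
        order = np.lexsort((np.arange(len(frac)), -frac))
        floors[order[:remainder]] += 1
    return floors


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to within-sample proportions (columns sum to 1)."""
    totals = table.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(f"zero-total samples: {list(zero.index)}")
    return FeatureTable(table.data / totals, provenance="relative")


def aggregate_by_group(
    table: FeatureTable,
    metadata: SampleMetadata,
    key: str,
    mode: str = "sum",
) -> FeatureTable:
    """Collapse samples into per-group profiles.

    ``sum`` adds counts within each group; ``mean`` averages columns
    (the natural choice when the input holds relative abundances).  The
    mode is recorded in the output's provenance.
    """
    if mode not in ("sum", "mean"):
        raise InputError(f"unknown aggregation mode: {mode!r}")
    groups = metadata.factor(key, table.sample_ids)
    if groups.isna().any():
        bad = groups[groups.isna()].index.tolist()
        raise MetadataError(f"samples without a {key!r} value: {bad}")
    agg = table.data.T.groupby(groups.astype(str).values).agg(mode).T
    return FeatureTable(agg, provenance=f"aggregated:{key}:{mode}")
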