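"""Shared data model, TSV readers/writers, and normalization utilities.

All abundance tables are oriented taxa x samples: taxa are rows, samples
are columns, everywhere in the package. Tables are tab-separated UTF-8
with '.' decimals and no quoting; lines starting with '#' are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaxonAbundanceTable",
    "SampleMetadata",
    "SoilProfile",
    "MetaboliteTable",
    "SOIL_VARIABLES",
    "read_abundance_tsv",
    "read_metadata_tsv",
    "read_soil_tsv",
    "read_metabolites_tsv",
    "to_relative",
    "zscore_normalize",
]

#: Soil physicochemistry variables carried by :class:`SoilProfile`:
#: pH (unitless), soil organic carbon (SOC), alkali-hydrolyzable
#: nitrogen (AN), available phosphorus (AP), available potassium (AK).
SOIL_VARIABLES = ("pH", "SOC", "AN", "AP", "AK")

#: Tolerance used when deciding whether column sums are "1" (relative data).
_RELATIVE_TOL = 1e-6


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} labels: {dupes}")


@dataclass
class TaxonAbundanceTable:
    """Taxon-by-sample abundance matrix with taxonomy labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix; index = taxon labels, columns = sample ids.
    kind : {"counts", "relative"}
        Whether entries are raw counts or per-sample fractions. For
        ``relative`` tables every sample column must sum to 1 (within 1e-9
        at construction after normalization; detection from files uses a
        looser 1e-6).
    rank : str
        Taxonomic rank of the row labels (e.g. ``"genus"``).
    """

    data: pd.DataFrame
    kind: str = "counts"
    rank: str = "genus"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("abundance table contains non-finite or missing entries")
        if values.size and (values < 0).any():
            raise ValueError("abundance table contains negative values")
        if self.kind == "relative" and values.size:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("relative table has sample columns not summing to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """taxa x samples matrix as float ndarray."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_taxa(self, taxa) -> "TaxonAbundanceTable":
        return TaxonAbundanceTable(self.data.loc[list(taxa)], kind=self.kind, rank=self.rank)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class SampleMetadata:
    """Sample -> site/group assignment (one group per sample)."""

    groups: pd.Series  # index = sample_id, values = group label

    def __post_init__(self) -> None:
        _check_unique(self.groups.index, "sample")
        if self.groups.isna().any():
            raise ValueError("metadata contains missing group labels")
        self.groups = self.groups.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    def group_of(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing}")
        return self.groups.loc[list(sample_ids)].to_numpy()

    def to_tsv(self, path) -> None:
        df = self.groups.rename("group").to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class SoilProfile:
    """Per-sample soil physicochemistry (pH, SOC, AN, AP, AK).

    pH must lie in (0, 14); the other variables are non-negative
    concentrations in the units of the originating assay.
    """

    data: pd.DataFrame  # index = sample_id, columns = SOIL_VARIABLES

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [v for v in SOIL_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValueError(f"soil table missing variables: {missing}")
        self.data = self.data.loc[:, list(SOIL_VARIABLES)].astype(float)
        ph = self.data["pH"]
        if ((ph <= 0) | (ph >= 14)).any():
            raise ValueError("pH values must lie strictly inside (0, 14)")
        others = self.data.drop(columns="pH")
        if (others.to_numpy() < 0).any():
            raise ValueError("soil variables other than pH must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class MetaboliteTable:
    """Per-sample tuber metabolite concentrations (mg/g dry weight)."""

    data: pd.DataFrame  # index = sample_id, columns = compounds

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        self.data = self.data.astype(float)
        if (self.data.to_numpy() < 0).any():
            raise ValueError("metabolite concentrations must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    return df


def read_abundance_tsv(
    path,
    kind_hint: str | None = None,
    rank: str = "genus",
    lineage_rank: int | None = None,
) -> TaxonAbundanceTable:
    """Read a taxa-x-samples TSV (first column = taxon label, header = sample ids).

    ``kind`` is inferred unless ``kind_hint`` is given: if every sample
    column sums to 1 within 1e-6 the table is taken as relative,
    otherwise as counts. When row labels are ';'-separated lineage
    strings, ``lineage_rank`` selects the component to use as the taxon
    label (rows collapsing to the same label are summed).
    """
    raw = _read_tsv(path)
    if lineage_rank is not None:
        labels = [
            s.split(";")[lineage_rank].strip() if ";" in s else s for s in raw.index
        ]
        raw = raw.astype(float).groupby(labels, sort=False).sum()
    try:
        df = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in abundance table {path}: {exc}") from exc
    if kind_hint is None:
        sums = df.to_numpy().sum(axis=0)
        kind = "relative" if np.allclose(sums, 1.0, atol=_RELATIVE_TOL) else "counts"
    else:
        kind = kind_hint
    return TaxonAbundanceTable(df, kind=kind, rank=rank)


def read_metadata_tsv(path) -> SampleMetadata:
    df = _read_tsv(path)
    if "group" not in df.columns:
        raise ValueError("metadata TSV must have a 'group' column")
    return SampleMetadata(df["group"])


def read_soil_tsv(path) -> SoilProfile:
    return SoilProfile(_read_tsv(path).astype(float))


def read_metabolites_tsv(path) -> MetaboliteTable:
    return MetaboliteTable(_read_tsv(path).astype(float))


def to_relative(table: TaxonAbundanceTable) -> TaxonAbundanceTable:
    """Convert counts to per-sample fractions (idempotent on relative tables)."""
    if table.kind == "relative":
        return table
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"cannot normalize zero-sum sample columns: {bad}")
    df = table.data.astype(float) / sums
    return TaxonAbundanceTable(df, kind="relative", rank=table.rank)


def zscore_normalize(matrix, axis: int = 1) -> np.ndarray:
    """Zero-mean / unit-variance normalization along ``axis`` (population sd).

    Each vector along the chosen axis is mapped to mean 0 and standard
    deviation 1. Constant vectors become all-zeros and a RuntimeWarning
    is emitted.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot z-score an empty matrix")
    mean = arr.mean(axis=axis, keepdims=True)
    sd = arr.std(axis=axis, keepdims=True)  # population sd (ddof=0)
    # exact-range test: a constant vector can still have sd > 0 from
    # floating-point cancellation in the mean
    constant = (np.ptp(arr, axis=axis, keepdims=True) == 0) | (sd == 0)
    if constant.any():
        warnings.warn(
            "constant vector(s) encountered during z-score normalization; mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    out = (arr - mean) / safe_sd
    return np.where(np.broadcast_to(constant, out.shape), 0.0, out)
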