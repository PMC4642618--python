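"""Omics data containers and delimited-text I/O.

A single omics source is a samples-by-features numeric matrix together with a
per-feature variable-type tag.  Expression sources are all-continuous; a
clinical ("phenome") table mixes continuous, ordinal, binary and multi-class
categorical variables, the latter pre-coded as integer level codes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ipf")

VAR_TYPES = ("continuous", "ordinal", "binary", "categorical")


@dataclass
class OmicsDataset:
    """One omics source: samples x features values plus variable-type tags.

    Parameters
    ----------
    name : str
        Free-text label of the source (e.g. ``"mRNA"``, ``"clinical"``).
    values : pandas.DataFrame
        Numeric matrix with sample ids as the index and feature ids as the
        columns.  Missing cells are ``NaN`` and are preserved, never imputed.
    var_types : pandas.Series
        Per-feature tag, one of ``continuous | ordinal | binary | categorical``,
        indexed by feature id.  Categorical features hold integer level codes.
    """

    name: str
    values: pd.DataFrame
    var_types: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.var_types is None:
            self.var_types = pd.Series(
                "continuous", index=self.values.columns, dtype=object
            )
        self.values = self.values.astype(float)
        self.var_types = self.var_types.reindex(self.values.columns)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    # ------------------------------------------------------------------
    def validate(self) -> None:
        idx = pd.Index(self.values.index)
        cols = pd.Index(self.values.columns)
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"{self.name}: duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"{self.name}: duplicate feature ids: {dups}")
        if self.var_types.isna().any():
            missing = list(self.var_types.index[self.var_types.isna()])
            raise ValueError(f"{self.name}: features without a type tag: {missing}")
        bad = set(self.var_types) - set(VAR_TYPES)
        if bad:
            raise ValueError(
                f"{self.name}: unknown variable type tag(s) {sorted(bad)}; "
                f"expected one of {VAR_TYPES}"
            )
        arr = self.values.to_numpy()
        if arr.size:
            if np.isnan(arr).all(axis=1).any():
                rows = [s for s, m in zip(self.sample_ids, np.isnan(arr).all(axis=1)) if m]
                raise ValueError(f"{self.name}: all-missing samples: {rows}")
            if np.isnan(arr).all(axis=0).any():
                feats = [f for f, m in zip(self.feature_ids, np.isnan(arr).all(axis=0)) if m]
                raise ValueError(f"{self.name}: all-missing features: {feats}")
        for fid in self.var_types.index[self.var_types == "binary"]:
            levels = self.values[fid].dropna().unique()
            if len(levels) > 2:
                raise ValueError(
                    f"{self.name}: binary feature {fid!r} has {len(levels)} levels"
                )

    # ------------------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsDataset":
        return OmicsDataset(
            self.name, self.values.loc[list(sample_ids)].copy(), self.var_types.copy()
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsDataset":
        ids = list(feature_ids)
        return OmicsDataset(self.name, self.values[ids].copy(), self.var_types[ids].copy())

    def copy(self) -> "OmicsDataset":
        return OmicsDataset(self.name, self.values.copy(), self.var_types.copy())

    # ------------------------------------------------------------------
    def write(self, path: str | Path, types_path: str | Path | None = None, sep: str = "\t") -> None:
        """Write the matrix (and optionally the type sidecar) as delimited text."""
        self.values.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")
        if types_path is not None:
            self.var_types.rename("type").to_csv(
                types_path, sep="\t", index_label="feature_id"
            )


def read_omics(
    path: str | Path,
    types_path: str | Path | None = None,
    name: str | None = None,
    sep: str | None = None,
    encode_strings: bool = False,
) -> OmicsDataset:
    """Read a samples-by-features matrix (header = feature ids, first column =
    sample ids).  Missing cells may be empty or ``NA``.

    ``types_path`` points to a two-column TSV mapping feature id to variable
    type; without it every feature is tagged continuous.  With
    ``encode_strings=True`` string levels in categorical columns are mapped to
    integer codes (mapping logged).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)

    var_types = None
    if types_path is not None:
        tmap = pd.read_csv(types_path, sep="\t", index_col=0).iloc[:, 0].astype(str)
        tmap.index = tmap.index.astype(str)
        unknown = set(tmap) - set(VAR_TYPES)
        if unknown:
            raise ValueError(f"unknown variable type tag(s) in {types_path}: {sorted(unknown)}")
        missing = [c for c in df.columns if c not in tmap.index]
        if missing:
            raise ValueError(f"features missing from type file: {missing}")
        var_types = tmap.reindex(df.columns)

    if encode_strings and var_types is not None:
        for fid in var_types.index[var_types == "categorical"]:
            col = df[fid]
            if col.dtype == object:
                levels = sorted(col.dropna().unique())
                mapping = {lev: i for i, lev in enumerate(levels)}
                logger.info("encoding %s levels %s", fid, mapping)
                df[fid] = col.map(mapping)

    # locate any non-numeric cell precisely before the blanket cast
    for fid in df.columns:
        coerced = pd.to_numeric(df[fid], errors="coerce")
        bad = coerced.isna() & df[fid].notna()
        if bad.any():
            where = [(s, fid) for s in df.index[bad]]
            raise ValueError(f"non-numeric cell(s) at (sample, feature): {where[:5]}")
        df[fid] = coerced

    return OmicsDataset(name or path.stem, df, var_types)


def align_samples(datasets: Iterable[OmicsDataset]) -> list[OmicsDataset]:
    """Restrict every dataset to the common samples, in lexicographic id order.

    The intersection of sample ids across all sources defines the cohort the
    integrated analysis runs on; order is canonicalised so that row j means the
    same patient in every source.
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ValueError("align_samples needs at least 2 datasets")
    common: set[str] = set(datasets[0].sample_ids)
    for ds in datasets[1:]:
        common &= set(ds.sample_ids)
    if not common:
        raise ValueError("no samples shared by all datasets")
    order = sorted(common)
    dropped = {ds.name: len(ds.sample_ids) - len(order) for ds in datasets}
    if any(dropped.values()):
        logger.info("align_samples dropped per dataset: %s", dropped)
    return [ds.subset_samples(order) for ds in datasets]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    """Write cluster labels as a two-column TSV (sample_id, cluster)."""
    labels.rename("cluster").to_csv(path, sep="\t", index_label="sample_id")
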