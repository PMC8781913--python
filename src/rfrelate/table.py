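"""Sample x feature intensity tables with attached metadata.

The :class:`FeatureTable` is the common currency of the pipeline: a
nonnegative intensity matrix (samples as rows, LC-MS features as columns,
missing cells allowed) together with per-sample metadata (class labels for
one or more classification levels, measurement batch, year) and per-feature
metadata (m/z, retention time, adduct label and an optional adduct-group id
used for consolidating multiple ionized forms of one compound).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]


@dataclass
class FeatureTable:
    """Intensity matrix plus sample/feature metadata.

    Parameters
    ----------
    intensities
        DataFrame, index = sample ids, columns = feature ids.  ``NaN``
        marks a missing cell.  Raw tables hold nonnegative intensities;
        after batch-wise autoscaling the cells are z-scores.
    sample_meta
        DataFrame indexed like ``intensities`` rows.  Conventional columns:
        one column per label scheme (e.g. ``origin``, ``variety``; ``NaN``
        where a sample carries no label for that scheme), ``batch`` and
        optionally ``year``.
    feature_meta
        DataFrame indexed like ``intensities`` columns.  Conventional
        columns: ``mz``, ``rt``, ``adduct_label``, ``adduct_group_id``.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)
    feature_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.intensities.index)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.intensities.columns)
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    def values(self) -> np.ndarray:
        """Intensity matrix as a float64 array (NaN = missing)."""
        return self.intensities.to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.intensities.isna().any().any())

    def labels(self, scheme: str) -> pd.Series:
        """Class labels of one scheme, aligned to the sample index."""
        if scheme not in self.sample_meta.columns:
            raise KeyError(f"no label scheme {scheme!r} in sample metadata")
        return self.sample_meta[scheme]

    # -- validation / manipulation -------------------------------------
    def validate(self) -> None:
        if not self.sample_meta.index.equals(self.intensities.index):
            raise ValueError("sample_meta index does not match intensity rows")
        if not self.feature_meta.index.equals(self.intensities.columns):
            raise ValueError("feature_meta index does not match intensity columns")
        if self.intensities.columns.has_duplicates:
            raise ValueError("feature ids must be unique")
        if self.intensities.index.has_duplicates:
            raise ValueError("sample ids must be unique")

    def select_features(self, feature_ids) -> "FeatureTable":
        feature_ids = pd.Index(feature_ids)
        return FeatureTable(
            self.intensities.loc[:, feature_ids].copy(),
            self.sample_meta.copy(),
            self.feature_meta.loc[feature_ids].copy(),
        )

    def select_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = pd.Index(sample_ids)
        return FeatureTable(
            self.intensities.loc[sample_ids].copy(),
            self.sample_meta.loc[sample_ids].copy(),
            self.feature_meta.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )


def write_feature_table(table: FeatureTable, directory: str, prefix: str = "table") -> None:
    """Write a table as three CSVs: intensities, sample and feature metadata.

    Missing intensity cells are written as empty fields.
    """
    os.makedirs(directory, exist_ok=True)
    table.intensities.to_csv(os.path.join(directory, f"{prefix}_intensities.csv"))
    table.sample_meta.to_csv(os.path.join(directory, f"{prefix}_samples.csv"))
    table.feature_meta.to_csv(os.path.join(directory, f"{prefix}_features.csv"))


def read_feature_table(directory: str, prefix: str = "table") -> FeatureTable:
    """Read a table written by :func:`write_feature_table`.

    Empty fields and ``NA`` in the intensity CSV are read as missing.
    """
    intens = pd.read_csv(
        os.path.join(directory, f"{prefix}_intensities.csv"),
        index_col=0,
        na_values=["", "NA"],
        keep_default_na=True,
    )
    smeta = pd.read_csv(os.path.join(directory, f"{prefix}_samples.csv"), index_col=0)
    fmeta = pd.read_csv(os.path.join(directory, f"{prefix}_features.csv"), index_col=0)
    fmeta.index = fmeta.index.astype(str)
    intens.columns = intens.columns.astype(str)
    return FeatureTable(intens, smeta, fmeta)
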