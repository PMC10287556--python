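"""Shared in-memory containers for the multi-view analysis.

Every view (environment, symptoms, brain volumes, covariates) is held as a
:class:`FeatureTable`, a thin wrapper around a participants x features pandas
DataFrame in which missing values are NaN. Genotypes travel as a
:class:`GenotypeMatrix` pairing an effect-allele dosage matrix with a variant
annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "GenotypeMatrix"]


@dataclass
class FeatureTable:
    """A participants x features numeric table for one data view.

    Parameters
    ----------
    data
        DataFrame indexed by participant ID with one numeric column per
        feature. Missing entries are NaN.
    view_label
        Free-text name of the view ("environment", "symptoms", ...).
    """

    data: pd.DataFrame
    view_label: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate participant ID: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name: {dup!r}")
        self.data = self.data.astype(float, copy=False)

    @property
    def participant_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness mask, True where a value is missing."""
        return self.data.isna().to_numpy()

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select_participants(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[ids].copy(), self.view_label)

    def select_features(self, names) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(names)].copy(), self.view_label)

    def complete_cases(self) -> pd.Index:
        """IDs of participants with no missing value in any feature."""
        return self.data.index[~self.data.isna().any(axis=1)]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.view_label)


#: required columns of the variant annotation table
VARIANT_INFO_COLUMNS = ("chrom", "pos", "effect_allele", "other_allele", "gene", "maf", "info")


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages with per-variant annotations.

    ``dosages`` is a DataFrame (participants x variants) with values in
    [0, 2]; ``variant_info`` is indexed by variant ID and carries chrom, pos
    (1-based), effect_allele, other_allele, gene, maf and imputation info.
    """

    dosages: pd.DataFrame
    variant_info: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_INFO_COLUMNS if c not in self.variant_info.columns]
        if missing:
            raise ValueError(f"variant_info lacks columns: {missing}")
        if not self.dosages.columns.equals(self.variant_info.index):
            raise ValueError("dosage columns and variant_info index disagree")
        vals = self.dosages.to_numpy()
        if np.nanmin(vals, initial=0.0) < -1e-9 or np.nanmax(vals, initial=0.0) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        # positions must be sorted within each chromosome for windowed clumping
        for chrom, sub in self.variant_info.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not non-decreasing on chromosome {chrom}")

    @property
    def participant_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def select_participants(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[ids].copy(), self.variant_info.copy())

    def select_variants(self, ids) -> "GenotypeMatrix":
        ids = list(ids)
        return GenotypeMatrix(self.dosages.loc[:, ids].copy(), self.variant_info.loc[ids].copy())
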