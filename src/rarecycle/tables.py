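"""Validated in-memory containers for community and soil-chemistry tables.

Two tables flow through the whole pipeline:

* :class:`OTUTable` — an integer count matrix (samples x OTUs) with a crop
  label per sample and a semicolon-delimited taxonomy lineage per OTU.
* :class:`NutrientTable` — per-sample soil physicochemical variables in the
  units declared by :data:`NUTRIENT_UNITS`, with the same crop labels.

The canonical orientation is samples in rows, OTUs in columns; every
downstream computation assumes it and the constructors enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "NutrientTable",
    "TableFormatError",
    "NUTRIENT_VARIABLES",
    "MNC_VARIABLES",
    "NUTRIENT_UNITS",
]


class TableFormatError(ValueError):
    """A table violates its structural invariants (ids, signs, columns)."""


#: All thirteen soil variables, in canonical column order.
NUTRIENT_VARIABLES = [
    "pH", "salt", "BD", "SWC", "NH4_N", "NO3_N", "Olsen_P",
    "Avail_K", "AN", "TP", "TK", "TN", "SOC",
]

#: The seven variables entering the multi-nutrient cycling index.
MNC_VARIABLES = ["SOC", "TN", "TP", "TK", "Olsen_P", "Avail_K", "NO3_N"]

#: Units assumed for each variable (declared, not converted on read).
NUTRIENT_UNITS = {
    "pH": "unitless", "salt": "permille", "BD": "g cm-3", "SWC": "%",
    "NH4_N": "mg kg-1", "NO3_N": "mg kg-1", "Olsen_P": "mg kg-1",
    "Avail_K": "mg kg-1", "AN": "g kg-1", "TP": "g kg-1", "TK": "g kg-1",
    "TN": "g kg-1", "SOC": "g kg-1",
}


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what} id(s): {dups[:5]}")


@dataclass
class OTUTable:
    """Integer count matrix (samples x OTUs) with crop labels and taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = sample ids, columns = OTU ids.
    crop
        Per-sample crop label, aligned to ``counts.index``.
    taxonomy
        Per-OTU lineage string (semicolon-delimited ranks), aligned to
        ``counts.columns``. Missing entries are filled with ``"unclassified"``.
    """

    counts: pd.DataFrame
    crop: pd.Series
    taxonomy: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "OTU")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("counts must be numeric")
        if np.any(values < 0):
            raise TableFormatError("counts must be non-negative")
        if np.any(values != np.floor(values)):
            raise TableFormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

        self.crop = pd.Series(self.crop).reindex(self.counts.index)
        if self.crop.isna().any():
            missing = self.crop.index[self.crop.isna()].tolist()
            raise TableFormatError(f"samples without crop label: {missing[:5]}")
        self.crop = self.crop.astype(str)

        if self.taxonomy is None:
            self.taxonomy = pd.Series("unclassified", index=self.counts.columns)
        else:
            self.taxonomy = (
                pd.Series(self.taxonomy)
                .reindex(self.counts.columns)
                .fillna("unclassified")
                .astype(str)
            )

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def subset_otus(self, otu_ids) -> "OTUTable":
        """Column subset preserving counts, crop labels and taxonomy."""
        return OTUTable(
            counts=self.counts.loc[:, list(otu_ids)].copy(),
            crop=self.crop.copy(),
            taxonomy=self.taxonomy.loc[list(otu_ids)].copy(),
        )

    def subset_samples(self, sample_ids) -> "OTUTable":
        ids = list(sample_ids)
        return OTUTable(
            counts=self.counts.loc[ids].copy(),
            crop=self.crop.loc[ids].copy(),
            taxonomy=self.taxonomy.copy(),
        )

    def __eq__(self, other) -> bool:  # equality of content, used in round-trips
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.crop.equals(other.crop)
            and self.taxonomy.equals(other.taxonomy)
        )


@dataclass
class NutrientTable:
    """Per-sample soil physicochemical variables plus a crop label.

    ``data`` holds the thirteen canonical columns (:data:`NUTRIENT_VARIABLES`)
    indexed by sample id; all concentrations must be non-negative and the
    seven MNC variables must be present.
    """

    data: pd.DataFrame
    crop: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [v for v in MNC_VARIABLES if v not in self.data.columns]
        if missing:
            raise TableFormatError(f"missing MNC variable {missing[0]}")
        concentration_cols = [c for c in self.data.columns if c != "pH"]
        values = self.data[concentration_cols].to_numpy(dtype=float)
        if np.any(np.isnan(self.data.to_numpy(dtype=float))):
            raise TableFormatError("missing values are not allowed")
        if np.any(values < 0):
            raise TableFormatError("negative concentration encountered")
        # canonical column order for the columns we know about
        known = [c for c in NUTRIENT_VARIABLES if c in self.data.columns]
        extra = [c for c in self.data.columns if c not in NUTRIENT_VARIABLES]
        self.data = self.data[known + extra].astype(float)

        self.crop = pd.Series(self.crop).reindex(self.data.index)
        if self.crop.isna().any():
            missing_crop = self.crop.index[self.crop.isna()].tolist()
            raise TableFormatError(f"samples without crop label: {missing_crop[:5]}")
        self.crop = self.crop.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def subset_samples(self, sample_ids) -> "NutrientTable":
        ids = list(sample_ids)
        return NutrientTable(data=self.data.loc[ids].copy(), crop=self.crop.loc[ids].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, NutrientTable):
            return NotImplemented
        return self.data.equals(other.data) and self.crop.equals(other.crop)
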