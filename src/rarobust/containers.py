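"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every sample-metadata table must provide.
METADATA_COLUMNS = ("clutch", "treatment", "time_h", "assay")

#: Recognised value scales for an expression matrix.
SCALES = ("counts", "log2", "zscore")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    samples
        DataFrame indexed by sample id with columns ``clutch``,
        ``treatment``, ``time_h`` and ``assay``.
    scale
        One of ``"counts"``, ``"log2"`` or ``"zscore"``; every operation
        that changes the scale records the new one here.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata lacks columns {missing_cols}")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(
                f"metadata missing for sample(s): {missing.tolist()[:5]}"
            )
        # keep metadata aligned to and restricted to the value columns
        self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(gene_ids)]
        return ExpressionMatrix(self.values.loc[keep], self.samples.copy(), self.scale)

    def subset_samples(self, mask) -> "ExpressionMatrix":
        """Subset columns by a boolean mask or list over the metadata rows."""
        ids = self.samples.index[mask] if np.asarray(mask).dtype == bool else mask
        return ExpressionMatrix(
            self.values[list(ids)], self.samples.loc[list(ids)].copy(), self.scale
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(), self.scale)


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    ``records`` holds one row per (gene, sample, pre-amplification group,
    technical replicate) with the measured ``ct`` in cycles.  Three
    pre-amplification groups emulate primer pools that target the L
    homeolog, the S homeolog, and both; the per-gene Ct of a sample is
    later taken as the median over the three groups.
    """

    records: pd.DataFrame
    samples: pd.DataFrame
    housekeeping: str = "gapdh"

    REQUIRED = ("gene_id", "sample_id", "preamp_group", "tech_replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"CtTable records lack columns {missing}")
        if (self.records["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        hk = self.records[self.records["gene_id"] == self.housekeeping]
        samples_with_hk = set(hk["sample_id"])
        all_samples = set(self.records["sample_id"])
        if samples_with_hk != all_samples:
            absent = sorted(all_samples - samples_with_hk)
            raise ValueError(
                f"housekeeping gene {self.housekeeping!r} absent in samples {absent[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.records["gene_id"].unique())
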