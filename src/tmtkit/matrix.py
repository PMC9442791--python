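"""Feature-by-sample abundance matrix with plex/channel metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SAMPLE_META_COLUMNS = ("plex_id", "channel_id", "is_reference")


@dataclass
class AbundanceMatrix:
    """Features x samples matrix of reporter abundances.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (protein accession, peptide id or
        phosphosite key) with one column per sample. Missing values are NaN.
    samples
        DataFrame indexed by sample id with columns ``plex_id``,
        ``channel_id`` and boolean ``is_reference``. Row order matches the
        column order of ``values``.
    provenance
        Free-form record of scale factors and filter counts applied so far.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        missing_meta = [c for c in SAMPLE_META_COLUMNS if c not in self.samples.columns]
        if missing_meta:
            raise ValueError(f"sample metadata lacks columns: {missing_meta}")
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[list(self.values.columns)]
        if self.values.index.has_duplicates:
            raise ValueError("feature ids must be unique")

    # -- basic accessors ------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def plexes(self) -> list[str]:
        return list(dict.fromkeys(self.samples["plex_id"]))

    def plex_columns(self, plex_id: str) -> list[str]:
        return list(self.samples.index[self.samples["plex_id"] == plex_id])

    def reference_column(self, plex_id: str) -> str:
        mask = (self.samples["plex_id"] == plex_id) & self.samples["is_reference"]
        refs = list(self.samples.index[mask])
        if len(refs) != 1:
            raise ValueError(
                f"plex {plex_id!r} has {len(refs)} reference channels, expected 1"
            )
        return refs[0]

    def analytic_columns(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_reference"].astype(bool)])

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), self.samples.copy(), dict(self.provenance)
        )

    def subset_plex(self, plex_id: str) -> "AbundanceMatrix":
        cols = self.plex_columns(plex_id)
        return AbundanceMatrix(
            self.values[cols].copy(), self.samples.loc[cols].copy(), dict(self.provenance)
        )

    def drop_reference(self) -> "AbundanceMatrix":
        cols = self.analytic_columns()
        return AbundanceMatrix(
            self.values[cols].copy(), self.samples.loc[cols].copy(), dict(self.provenance)
        )

    def select_features(self, feature_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(feature_ids)
        return AbundanceMatrix(
            self.values.loc[ids].copy(), self.samples.copy(), dict(self.provenance)
        )

    def log2(self) -> pd.DataFrame:
        """Log2-transformed values; non-positive entries become NaN."""
        vals = self.values.where(self.values > 0)
        return np.log2(vals)

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", na_rep="NA", index_label="feature_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, samples_path: str | Path
    ) -> "AbundanceMatrix":
        values = pd.read_csv(
            values_path, sep="\t", index_col="feature_id", na_values=["NA"]
        )
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        samples["is_reference"] = samples["is_reference"].astype(bool)
        return cls(values, samples)


def concat_plexes(matrices: Iterable[AbundanceMatrix]) -> AbundanceMatrix:
    """Column-wise concatenation of per-plex matrices on the shared feature set."""
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices given")
    common = mats[0].feature_ids
    for m in mats[1:]:
        common = common.intersection(m.feature_ids)
    values = pd.concat([m.values.loc[common] for m in mats], axis=1)
    samples = pd.concat([m.samples for m in mats], axis=0)
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids across plexes")
    return AbundanceMatrix(values, samples)
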