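"""Shared domain types for the analysis pipeline.

All tabular payloads are pandas objects; thin dataclass wrappers carry the
metadata (dataset tags, masks, parameters) that the raw frames cannot.
Missing values are encoded as NaN in ``OmicsMatrix.values`` and are only
permitted for metabolome datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "DatasetTag",
    "OmicsMatrix",
    "SampleMetadata",
    "FilterReport",
    "DifferentialResult",
    "ModulePartition",
    "CombinedMatrix",
    "NetworkParams",
    "EigengeneTable",
    "ModuleAssociation",
    "GREY",
]

#: colour label for analytes left unassigned by module detection
GREY = "grey"


class DatasetTag(str, Enum):
    TRANSCRIPTOME = "transcriptome"
    METABOLOME_POS = "metabolome_pos"
    METABOLOME_NEG = "metabolome_neg"

    @property
    def is_metabolome(self) -> bool:
        return self in (DatasetTag.METABOLOME_POS, DatasetTag.METABOLOME_NEG)


@dataclass
class OmicsMatrix:
    """One dataset's analyte x sample abundance table.

    ``values``: DataFrame indexed by analyte id, columns = sample ids,
    non-negative reals, NaN = missing (metabolome only).
    """

    dataset_tag: DatasetTag
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.dataset_tag = DatasetTag(self.dataset_tag)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate analyte ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=np.inf) < 0:
            raise ValueError("negative abundance values are not allowed")
        if not self.dataset_tag.is_metabolome and np.isnan(arr).any():
            raise ValueError(
                f"missing values not permitted in {self.dataset_tag.value} dataset"
            )

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_analytes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_analytes(self, ids) -> "OmicsMatrix":
        return replace(self, values=self.values.loc[list(ids)])

    def subset_samples(self, ids) -> "OmicsMatrix":
        return replace(self, values=self.values.loc[:, list(ids)])


@dataclass
class SampleMetadata:
    """Per-sample design factors.

    ``table``: DataFrame indexed by sample id with columns
    ``diet`` (CON|HFD), ``exercise`` (pre|post), ``is_qc`` (bool),
    ``run_order`` (int). QC samples carry diet/exercise = "QC".
    """

    table: pd.DataFrame

    REQUIRED = ("diet", "exercise", "is_qc", "run_order")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        self.table = self.table.assign(is_qc=self.table["is_qc"].astype(bool))

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def qc_samples(self) -> pd.Index:
        return self.table.index[self.table["is_qc"]]

    @property
    def biological_samples(self) -> pd.Index:
        return self.table.index[~self.table["is_qc"]]

    def group_samples(self, factor: str, level: str) -> pd.Index:
        """Biological samples at ``level`` of ``factor`` (e.g. diet == HFD)."""
        tbl = self.table
        keep = (~tbl["is_qc"]) & (tbl[factor] == level)
        return tbl.index[keep]

    def indicator(self, factor: str, level: str, samples=None) -> pd.Series:
        samples = self.biological_samples if samples is None else pd.Index(samples)
        return (self.table.loc[samples, factor] == level).astype(float)


@dataclass
class FilterReport:
    """Per-analyte QC filter outcome.

    ``table`` columns: qc_rsd (percent, NaN when undefined),
    detection_fraction, kept (bool), removal_reason ({rsd, detection, none}).
    """

    dataset_tag: DatasetTag
    table: pd.DataFrame

    @property
    def kept_ids(self) -> pd.Index:
        return self.table.index[self.table["kept"]]

    @property
    def removed_ids(self) -> pd.Index:
        return self.table.index[~self.table["kept"]]

    @staticmethod
    def combine(a: "FilterReport", b: "FilterReport") -> "FilterReport":
        """Intersection of two reports' kept sets (order-invariant)."""
        if not a.table.index.equals(b.table.index):
            raise ValueError("filter reports cover different analyte sets")
        tbl = a.table.copy()
        tbl["kept"] = a.table["kept"] & b.table["kept"]
        reason = np.where(
            ~a.table["kept"], a.table["removal_reason"],
            np.where(~b.table["kept"], b.table["removal_reason"], "none"),
        )
        tbl["removal_reason"] = reason
        for col in ("qc_rsd", "detection_fraction"):
            if tbl[col].isna().all() and not b.table[col].isna().all():
                tbl[col] = b.table[col]
        return FilterReport(a.dataset_tag, tbl)


@dataclass
class DifferentialResult:
    """Per-analyte two-group comparison records.

    ``table`` columns: fold_change (signed ratio), ci_low, ci_high,
    p_raw, q_bh, direction ({up, down}); index = analyte id.
    """

    group_a: str
    group_b: str
    table: pd.DataFrame

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_bh"] < q_threshold]


@dataclass
class ModulePartition:
    """Analyte -> module colour mapping spanning datasets.

    ``table``: DataFrame indexed by analyte id with columns ``dataset``
    and ``module_colour``; grey = unassigned.
    """

    table: pd.DataFrame

    @property
    def analyte_ids(self) -> pd.Index:
        return self.table.index

    @property
    def colours(self) -> list[str]:
        """Module colours, grey excluded, in decreasing size order."""
        counts = self.table.loc[
            self.table["module_colour"] != GREY, "module_colour"
        ].value_counts()
        return counts.index.tolist()

    def members(self, colour: str) -> pd.Index:
        return self.table.index[self.table["module_colour"] == colour]

    def labels(self, ids=None) -> pd.Series:
        if ids is None:
            return self.table["module_colour"]
        return self.table.loc[list(ids), "module_colour"]


@dataclass
class CombinedMatrix:
    """Row-concatenated, per-analyte standardised multi-omics matrix.

    ``values``: analyte x sample, each row mean 0 / SD 1; ``dataset_of``
    maps analyte id -> dataset tag string. QC samples are excluded.
    """

    values: pd.DataFrame
    dataset_of: pd.Series

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("combined matrix must be complete")
        mu = arr.mean(axis=1)
        sd = arr.std(axis=1, ddof=0)
        if np.abs(mu).max(initial=0.0) > 1e-8 or np.abs(sd - 1).max(initial=0.0) > 1e-8:
            raise ValueError("combined matrix rows must be mean 0 / SD 1")

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class NetworkParams:
    beta: int = 6
    network_sign: str = "unsigned"  # or "signed"
    min_module_size: int = 20
    merge_cut_height: float = 0.25
    deep_split: int = 2
    #: analytes whose |cor| with their module eigengene falls below this
    #: are returned to grey (0 disables the purge)
    kme_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError("network_sign must be 'unsigned' or 'signed'")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must be in [0, 1]")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if not 0 <= self.kme_threshold < 1:
            raise ValueError("kme_threshold must be in [0, 1)")


@dataclass
class EigengeneTable:
    """Module eigengenes: module colour x sample scores.

    ``values``: DataFrame indexed by module colour, columns = sample ids.
    ``variance_explained``: Series per module colour.
    """

    values: pd.DataFrame
    variance_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def module_colours(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ModuleAssociation:
    """Module x design-factor association table.

    ``table``: indexed by module colour with columns diet_cor, diet_p,
    diet_q, exercise_cor, exercise_p, exercise_q, interaction_p,
    flagged_of_interest (bool).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def flagged(self) -> pd.Index:
        return self.table.index[self.table["flagged_of_interest"]]
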