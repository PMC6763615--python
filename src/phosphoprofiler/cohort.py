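"""Cohort container: a samples x analytes matrix with sample metadata."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

_META_COLUMNS = ("group", "patient_id", "timepoint")


@dataclass
class CohortMatrix:
    """Samples x analytes matrix of a chosen profile view plus metadata.

    ``values`` is indexed by sample id with one column per analyte.
    ``sample_meta`` shares the index and carries ``group`` (diagnostic
    group label), ``patient_id`` and ``timepoint``. Missing cells are
    rejected outright: imputation is out of scope.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"group": "all", "patient_id": self.values.index, "timepoint": 0},
                index=self.values.index,
            )
        if not self.values.index.equals(self.sample_meta.index):
            raise DataError("values and sample_meta must share the same sample index")
        if "group" not in self.sample_meta.columns:
            raise DataError("sample_meta must contain a 'group' column")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise DataError(f"cohort matrix contains missing cells in analytes: {bad}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise DataError("cohort matrix must be numeric")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def subset_analytes(self, analytes: list[str]) -> "CohortMatrix":
        return CohortMatrix(self.values[analytes].copy(), self.sample_meta.copy())

    # -- I/O: one CSV with leading metadata columns ------------------------

    def to_csv(self) -> str:
        meta = self.sample_meta.reindex(columns=list(_META_COLUMNS), fill_value="")
        out = pd.concat([meta, self.values], axis=1)
        out.index.name = "sample_id"
        buf = io.StringIO()
        out.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "CohortMatrix":
        df = pd.read_csv(io.StringIO(text), index_col="sample_id")
        df.index.name = None
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if "group" in missing:
            raise DataError("cohort CSV is missing the 'group' metadata column")
        meta_cols = [c for c in _META_COLUMNS if c in df.columns]
        meta = df[meta_cols]
        values = df.drop(columns=meta_cols).astype(float)
        return cls(values, meta)
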