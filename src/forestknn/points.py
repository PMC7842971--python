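"""Sample-point container shared by the sampling, index and modeling layers.

A :class:`SamplePoints` wraps a pandas DataFrame whose rows are cell
centroids drawn from a grid: coordinates, grid indices, stratum label (when
produced by stratified sampling), optional fold assignment, and any number
of named value columns (extracted responses/predictors or computed
indices).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SamplePoints"]

#: columns that are bookkeeping, not extracted/derived values
STRUCTURAL_COLUMNS = ("id", "x", "y", "row", "col", "stratum", "fold")


@dataclass
class SamplePoints:
    """Cell-centroid point records with named value columns."""

    data: pd.DataFrame
    crs_id: str = ""

    def __post_init__(self) -> None:
        df = self.data
        for col in ("x", "y"):
            if col not in df.columns:
                raise ValueError(f"SamplePoints data must have an {col!r} column")
        if "id" not in df.columns:
            df = df.copy()
            df.insert(0, "id", range(len(df)))
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in STRUCTURAL_COLUMNS]

    def values_frame(self, columns: list[str] | None = None) -> pd.DataFrame:
        """The value columns as a plain DataFrame (rows aligned with points)."""
        return self.data[columns if columns is not None else self.value_columns].copy()

    def with_columns(self, frame: pd.DataFrame) -> "SamplePoints":
        """New SamplePoints with extra/overwritten value columns."""
        if len(frame) != len(self.data):
            raise ValueError("column frame length does not match point count")
        df = self.data.copy()
        for col in frame.columns:
            df[col] = frame[col].to_numpy()
        return SamplePoints(df, crs_id=self.crs_id)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike, crs_id: str = "") -> "SamplePoints":
        return cls(pd.read_csv(path), crs_id=crs_id)
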