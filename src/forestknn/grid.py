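"""Gridded raster data model.

A :class:`GridRaster` is the package's universal raster currency: an
``(n_bands, n_rows, n_cols)`` float array on a north-up regular grid, with
missing cells represented as NaN in memory (the ``nodata`` attribute records
the sentinel used on disk).  A :class:`GridSpec` describes the grid alone —
two rasters are *aligned* iff their specs match.

Coordinate conventions: map x increases with column index, map y decreases
with row index (north-up); ``origin_x``/``origin_y`` locate the outer corner
of the upper-left cell; cell centers sit at half-cell offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["GridSpec", "GridRaster"]

#: relative tolerance for grid-coordinate comparisons
_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular north-up grid (no cell values).

    Fully determines cell-center coordinates: column ``j`` has center
    ``origin_x + (j + 0.5) * cell_size_x`` and row ``i`` has center
    ``origin_y - (i + 0.5) * cell_size_y``.
    """

    origin_x: float
    origin_y: float
    cell_size_x: float
    cell_size_y: float
    n_rows: int
    n_cols: int
    crs_id: str = ""

    def __post_init__(self) -> None:
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise ValueError("cell sizes must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    # -- geometry -----------------------------------------------------------

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size_y,
            self.origin_x + self.n_cols * self.cell_size_x,
            self.origin_y,
        )

    def cell_center(self, row, col):
        """Map coordinates of cell centers (vectorized)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.cell_size_x
        y = self.origin_y - (row + 0.5) * self.cell_size_y
        return x, y

    def index_of(self, x, y):
        """Row/col of the cell containing map point(s) (x, y).

        Returned as float arrays of integer value; callers clip or mask
        out-of-extent indices themselves.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size_x)
        row = np.floor((self.origin_y - y) / self.cell_size_y)
        return row, col

    def matches(self, other: "GridSpec", check_crs: bool = True) -> bool:
        """True if the two specs describe the same grid (tolerant compare)."""
        scale = max(self.cell_size_x, self.cell_size_y)
        same = (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.origin_x, other.origin_x, rtol=0, atol=_GRID_RTOL * abs(self.origin_x) + 1e-6 * scale)
            and np.isclose(self.origin_y, other.origin_y, rtol=0, atol=_GRID_RTOL * abs(self.origin_y) + 1e-6 * scale)
            and np.isclose(self.cell_size_x, other.cell_size_x, rtol=_GRID_RTOL)
            and np.isclose(self.cell_size_y, other.cell_size_y, rtol=_GRID_RTOL)
        )
        if check_crs:
            same = same and self.crs_id == other.crs_id
        return bool(same)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin_x": self.origin_x,
                "origin_y": self.origin_y,
                "cell_size_x": self.cell_size_x,
                "cell_size_y": self.cell_size_y,
                "n_rows": self.n_rows,
                "n_cols": self.n_cols,
                "crs_id": self.crs_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        return cls(**json.loads(text))


@dataclass
class GridRaster:
    """n-band gridded values with geotransform, CRS tag and NoData handling.

    ``values`` is always ``(n_bands, n_rows, n_cols)`` float; missing cells
    are NaN regardless of the on-disk sentinel stored in ``nodata``.
    """

    values: np.ndarray
    band_names: list[str]
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size_x: float = 1.0
    cell_size_y: float = 1.0
    crs_id: str = ""
    nodata: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError("values must be 2-D or (band, row, col) 3-D")
        if self.nodata is not None and not np.isnan(self.nodata):
            arr = np.where(arr == self.nodata, np.nan, arr)
        self.values = arr
        self.band_names = list(self.band_names)
        if len(self.band_names) != arr.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for {arr.shape[0]} bands"
            )
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise ValueError("cell sizes must be positive")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_spec(
        cls,
        values: np.ndarray,
        band_names: Sequence[str],
        spec: GridSpec,
        nodata: float | None = None,
    ) -> "GridRaster":
        r = cls(
            values=values,
            band_names=list(band_names),
            origin_x=spec.origin_x,
            origin_y=spec.origin_y,
            cell_size_x=spec.cell_size_x,
            cell_size_y=spec.cell_size_y,
            crs_id=spec.crs_id,
            nodata=nodata,
        )
        if r.n_rows != spec.n_rows or r.n_cols != spec.n_cols:
            raise ValueError("array shape does not match GridSpec row/col counts")
        return r

    def with_values(self, values: np.ndarray, band_names: Sequence[str] | None = None) -> "GridRaster":
        """New raster on the same grid with different values."""
        return GridRaster(
            values=values,
            band_names=list(band_names) if band_names is not None else list(self.band_names),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size_x=self.cell_size_x,
            cell_size_y=self.cell_size_y,
            crs_id=self.crs_id,
            nodata=self.nodata,
        )

    # -- properties ---------------------------------------------------------

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size_x=self.cell_size_x,
            cell_size_y=self.cell_size_y,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            crs_id=self.crs_id,
        )

    def band(self, name: str) -> np.ndarray:
        """2-D view of one band by name."""
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"no band named {name!r}; have {self.band_names}") from None
        return self.values[idx]

    def select_bands(self, names: Sequence[str]) -> "GridRaster":
        idx = [self.band_names.index(n) for n in names]
        return self.with_values(self.values[idx], band_names=list(names))

    def finite_mask(self) -> np.ndarray:
        """2-D bool mask of cells finite in every band."""
        return np.all(np.isfinite(self.values), axis=0)

    def aligned_with(self, other: "GridRaster | GridSpec") -> bool:
        spec = other if isinstance(other, GridSpec) else other.spec
        return self.spec.matches(spec)
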