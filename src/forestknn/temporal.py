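"""Temporal summary metrics of annual raster time series.

An annual series of index rasters is reduced per pixel to robust summary
statistics — median, interquartile range (IQR) and the Theil–Sen slope
(median of all pairwise slopes, a trend estimator insensitive to outlier
years) — plus any user-registered reducer.  These summaries are the
spectral-trend predictors fed to the imputation model.

The Theil–Sen slope uses actual calendar-year spacings, so a series with
missing years still yields slopes in units of value per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

from .grid import GridRaster
from .points import SamplePoints

__all__ = [
    "RasterTimeSeries",
    "theil_sen_slope",
    "temporal_summary",
    "temporal_summary_points",
    "register_metric",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS = ("median", "IQR", "theil_sen")


@dataclass
class RasterTimeSeries:
    """Ordered, grid-aligned annual stack of rasters.

    Layers are sorted by year on construction; years must be unique.  All
    layers must share one grid and one band list.
    """

    layers: list[GridRaster]
    years: list[int]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.years):
            raise ValueError("one year per layer required")
        if len(set(self.years)) != len(self.years):
            raise ValueError("years must be unique")
        order = np.argsort(self.years)
        self.layers = [self.layers[i] for i in order]
        self.years = [int(self.years[i]) for i in order]
        spec = self.layers[0].spec
        names = self.layers[0].band_names
        for lyr in self.layers[1:]:
            if not lyr.spec.matches(spec):
                raise ValueError("time-series layers are not grid-aligned")
            if lyr.band_names != names:
                raise ValueError("time-series layers have differing band names")

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def band_names(self) -> list[str]:
        return self.layers[0].band_names

    def stack(self, band: str) -> np.ndarray:
        """(n_years, n_rows, n_cols) array for one band."""
        return np.stack([lyr.band(band) for lyr in self.layers])


def theil_sen_slope(values: Sequence[float], times: Sequence[float]) -> float:
    """Median of all pairwise slopes (y_j - y_i)/(t_j - t_i), i < j.

    Missing (NaN) pairs are dropped; fewer than two finite pairs yields NaN
    rather than raising, so the raster path degrades gracefully.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if y.size < 2:
        return float("nan")
    i, j = np.triu_indices(y.size, k=1)
    slopes = (y[j] - y[i]) / (t[j] - t[i])
    return float(np.median(slopes))


# -- metric registry --------------------------------------------------------
# Built-ins have a vectorized implementation over a (T, N) stack; registered
# reducers receive the finite values (and paired years) of one pixel.


def _stack_median(stack: np.ndarray, years: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(stack, axis=0)


def _stack_iqr(stack: np.ndarray, years: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q75, q25 = np.nanpercentile(stack, [75, 25], axis=0)
    return q75 - q25


def _stack_theil_sen(stack: np.ndarray, years: np.ndarray) -> np.ndarray:
    T = stack.shape[0]
    i, j = np.triu_indices(T, k=1)
    with np.errstate(invalid="ignore"):
        slopes = (stack[j] - stack[i]) / (years[j] - years[i])[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(slopes, axis=0)
    # a single finite year produces no pair: nanmedian already yields NaN
    return out

_BUILTIN_METRICS: dict[str, Callable] = {
    "median": _stack_median,
    "IQR": _stack_iqr,
    "theil_sen": _stack_theil_sen,
}

_USER_METRICS: dict[str, Callable] = {}


def register_metric(name: str, reducer: Callable[..., float]) -> None:
    """Register a per-pixel reducer usable in :func:`temporal_summary`.

    The reducer is called as ``reducer(values)`` or, if it accepts two
    arguments, ``reducer(values, years)`` with the finite values of one
    pixel and their calendar years.
    """
    if name in _BUILTIN_METRICS or name in _USER_METRICS:
        raise ValueError(f"metric {name!r} is already registered")
    _USER_METRICS[name] = reducer


def _apply_user_metric(reducer: Callable, stack: np.ndarray, years: np.ndarray) -> np.ndarray:
    T, N = stack.shape
    out = np.full(N, np.nan)
    finite = np.isfinite(stack)
    import inspect

    try:
        params = inspect.signature(reducer).parameters.values()
        required = [
            p for p in params
            if p.default is inspect.Parameter.empty
            and p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        ]
        two_args = len(required) >= 2
    except (TypeError, ValueError):
        two_args = False
    for n in range(N):
        ok = finite[:, n]
        if not ok.any():
            continue
        vals = stack[ok, n]
        out[n] = reducer(vals, years[ok]) if two_args else reducer(vals)
    return out


def _summarize_stack(
    stack: np.ndarray, years: np.ndarray, metrics: Sequence[str], min_valid: int
) -> list[np.ndarray]:
    """Reduce a (T, N) stack to one length-N array per metric."""
    n_valid = np.isfinite(stack).sum(axis=0)
    invalid = n_valid < min_valid
    outs = []
    for m in metrics:
        if m in _BUILTIN_METRICS:
            arr = _BUILTIN_METRICS[m](stack, years)
        elif m in _USER_METRICS:
            arr = _apply_user_metric(_USER_METRICS[m], stack, years)
        else:
            raise ValueError(
                f"unknown metric {m!r}; known: {sorted(_BUILTIN_METRICS) + sorted(_USER_METRICS)}"
            )
        arr = np.asarray(arr, dtype=float).copy()
        arr[invalid] = np.nan
        outs.append(arr)
    return outs


def temporal_summary(
    series: RasterTimeSeries,
    metrics: Sequence[str] = DEFAULT_METRICS,
    min_valid: int = 3,
    block_rows: int | None = None,
) -> GridRaster:
    """Per-pixel temporal summaries of each band of an annual series.

    Returns one band per (input band x metric), named ``<band>_<metric>``.
    Pixels with fewer than ``min_valid`` finite years are NoData (default 3:
    a slope from two points is a single pairwise ratio with no median
    smoothing).  ``block_rows`` bounds memory by processing row blocks;
    the result is identical for any block size.
    """
    if not metrics:
        raise ValueError("metrics must be non-empty")
    if min_valid < 2:
        raise ValueError("min_valid must be >= 2")
    first = series.layers[0]
    years = np.asarray(series.years, dtype=float)
    n_rows, n_cols = first.n_rows, first.n_cols
    if block_rows is None or block_rows > n_rows:
        block_rows = n_rows

    out_bands = []
    out_names = []
    for band in series.band_names:
        stack3 = series.stack(band)  # (T, rows, cols)
        results = [np.full((n_rows, n_cols), np.nan) for _ in metrics]
        for r0 in range(0, n_rows, block_rows):
            r1 = min(r0 + block_rows, n_rows)
            block = stack3[:, r0:r1, :].reshape(len(series), -1)
            pieces = _summarize_stack(block, years, metrics, min_valid)
            for res, piece in zip(results, pieces):
                res[r0:r1, :] = piece.reshape(r1 - r0, n_cols)
        out_bands.extend(results)
        out_names.extend(f"{band}_{m}" for m in metrics)
    return first.with_values(np.stack(out_bands), band_names=out_names)


def temporal_summary_points(
    series: Union[pd.DataFrame, SamplePoints],
    years: Sequence[int],
    columns: Sequence[str] | None = None,
    metrics: Sequence[str] = DEFAULT_METRICS,
    min_valid: int = 3,
    prefix: str | None = None,
) -> pd.DataFrame:
    """Point-table counterpart of :func:`temporal_summary`.

    ``series`` holds one column per year (``columns`` orders them to match
    ``years``); the result has one column per metric named
    ``<prefix>_<metric>``.
    """
    df = series.data if isinstance(series, SamplePoints) else series
    if columns is None:
        columns = [str(y) for y in years]
    stack = df[list(columns)].to_numpy(dtype=float).T  # (T, N)
    yr = np.asarray(years, dtype=float)
    order = np.argsort(yr)
    stack, yr = stack[order], yr[order]
    pieces = _summarize_stack(stack, yr, metrics, min_valid)
    name = prefix if prefix is not None else "series"
    return pd.DataFrame({f"{name}_{m}": p for m, p in zip(metrics, pieces)})
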