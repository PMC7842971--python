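"""Raster harmonization operators.

These put heterogeneous layers (responses, imagery, terrain, masks) onto a
single analysis grid before modeling: resampling to a reference grid,
extent matching with optional masking, moving-window filtering, NoData
edge buffering, and tiling/mosaicking for memory-bounded processing.

All operators are NoData-aware (NaN in memory) and same-CRS: layers in a
different coordinate system must be reprojected upstream.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .grid import GridRaster, GridSpec

__all__ = [
    "match_resolution",
    "match_extent",
    "focal_multiband",
    "edges",
    "tile",
    "mosaic",
]

log = logging.getLogger(__name__)


def _check_overlap(input_extent, ref_extent) -> None:
    ix0, iy0, ix1, iy1 = input_extent
    rx0, ry0, rx1, ry1 = ref_extent
    if ix1 <= rx0 or rx1 <= ix0 or iy1 <= ry0 or ry1 <= iy0:
        raise ValueError(
            f"input footprint {input_extent} does not overlap reference extent {ref_extent}"
        )


def match_resolution(
    input: GridRaster, reference: GridSpec, method: str = "bilinear"
) -> GridRaster:
    """Resample a raster onto a reference grid (cell-center semantics).

    ``method`` is ``"bilinear"`` for continuous layers or ``"nearest"`` for
    categorical ones (masks, land cover).  Bilinear weights are renormalized
    over the finite support; a target cell whose entire support is NoData
    (or that falls outside the input footprint) is NoData.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    if input.crs_id != reference.crs_id:
        raise ValueError(
            f"CRS mismatch: input {input.crs_id!r} vs reference {reference.crs_id!r}; "
            "reproject upstream before resampling"
        )
    if not np.any(np.isfinite(input.values)):
        raise ValueError("input raster has no finite cell")
    _check_overlap(input.spec.extent, reference.extent)

    rows = np.arange(reference.n_rows)
    cols = np.arange(reference.n_cols)
    xs, _ = reference.cell_center(np.zeros_like(cols), cols)
    _, ys = reference.cell_center(rows, np.zeros_like(rows))
    # fractional position of reference centers in input index space
    fc = (xs - input.origin_x) / input.cell_size_x - 0.5
    fr = (input.origin_y - ys) / input.cell_size_y - 0.5
    FR, FC = np.meshgrid(fr, fc, indexing="ij")

    nb, nr, nc = input.values.shape
    out = np.full((nb, reference.n_rows, reference.n_cols), np.nan)

    if method == "nearest":
        ri = np.rint(FR).astype(int)
        ci = np.rint(FC).astype(int)
        inside = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
        rj = np.clip(ri, 0, nr - 1)
        cj = np.clip(ci, 0, nc - 1)
        for b in range(nb):
            vals = input.values[b][rj, cj]
            out[b] = np.where(inside, vals, np.nan)
    else:
        r0 = np.floor(FR).astype(int)
        c0 = np.floor(FC).astype(int)
        dr = FR - r0
        dc = FC - c0
        # support outside the input grid contributes weight to nothing
        inside_any = (FR > -0.5 - 1e-9) & (FR < nr - 0.5 + 1e-9) & (
            FC > -0.5 - 1e-9
        ) & (FC < nc - 0.5 + 1e-9)
        corners = [
            (r0, c0, (1 - dr) * (1 - dc)),
            (r0, c0 + 1, (1 - dr) * dc),
            (r0 + 1, c0, dr * (1 - dc)),
            (r0 + 1, c0 + 1, dr * dc),
        ]
        for b in range(nb):
            acc = np.zeros(FR.shape)
            wsum = np.zeros(FR.shape)
            for rr, cc, w in corners:
                valid = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
                rj = np.clip(rr, 0, nr - 1)
                cj = np.clip(cc, 0, nc - 1)
                v = input.values[b][rj, cj]
                ok = valid & np.isfinite(v) & (w > 0)
                acc += np.where(ok, w * np.where(np.isfinite(v), v, 0.0), 0.0)
                wsum += np.where(ok, w, 0.0)
            with np.errstate(invalid="ignore"):
                band = acc / wsum
            band[wsum <= 0] = np.nan
            band[~inside_any] = np.nan
            out[b] = band

    result = GridRaster.from_spec(out, input.band_names, reference, nodata=input.nodata)
    log.info("match_resolution: %s -> %s", input.spec, reference)
    return result


def match_extent(
    input: GridRaster, reference: GridRaster, mask_nodata: bool = False
) -> GridRaster:
    """Crop/pad a raster to a reference's extent (grids must be aligned in
    CRS, resolution and origin phase); optionally propagate the reference's
    NoData cells into the output."""
    if input.crs_id != reference.crs_id:
        raise ValueError(
            f"CRS mismatch: {input.crs_id!r} vs {reference.crs_id!r}"
        )
    if not (
        np.isclose(input.cell_size_x, reference.cell_size_x)
        and np.isclose(input.cell_size_y, reference.cell_size_y)
    ):
        raise ValueError(
            "resolution mismatch: call match_resolution first "
            f"({input.cell_size_x}x{input.cell_size_y} vs "
            f"{reference.cell_size_x}x{reference.cell_size_y})"
        )
    col_off = (reference.origin_x - input.origin_x) / input.cell_size_x
    row_off = (input.origin_y - reference.origin_y) / input.cell_size_y
    if not (
        np.isclose(col_off, np.rint(col_off), atol=1e-6)
        and np.isclose(row_off, np.rint(row_off), atol=1e-6)
    ):
        raise ValueError("grids are not phase-aligned: call match_resolution first")
    col_off = int(np.rint(col_off))
    row_off = int(np.rint(row_off))
    _check_overlap(input.spec.extent, reference.spec.extent)

    nb = input.n_bands
    out = np.full((nb, reference.n_rows, reference.n_cols), np.nan)
    # overlapping window in both index spaces
    r0 = max(row_off, 0)
    c0 = max(col_off, 0)
    r1 = min(row_off + reference.n_rows, input.n_rows)
    c1 = min(col_off + reference.n_cols, input.n_cols)
    if r1 > r0 and c1 > c0:
        out[:, r0 - row_off : r1 - row_off, c0 - col_off : c1 - col_off] = input.values[
            :, r0:r1, c0:c1
        ]
    if mask_nodata:
        ref_missing = ~reference.finite_mask()
        out[:, ref_missing] = np.nan
    return GridRaster.from_spec(out, input.band_names, reference.spec, nodata=input.nodata)


_FOCAL_STATS: dict[str, tuple[Callable, Callable]] = {
    # name -> (propagate reducer, NaN-ignoring reducer)
    "mean": (np.mean, np.nanmean),
    "median": (np.median, np.nanmedian),
}


def focal_multiband(
    input: GridRaster,
    window: int,
    statistic: str | Callable = "mean",
    na_policy: str = "propagate",
) -> GridRaster:
    """Moving-window filter applied independently to each band.

    ``window`` must be odd; ``statistic`` is ``"mean"``, ``"median"`` or a
    callable reducing a 1-D window sample to a scalar.  With
    ``na_policy="propagate"`` any NoData in the window makes the cell NoData
    (conservative default); ``"ignore"`` reduces over the finite values
    only.  Cells that are NoData in the input stay NoData either way, so
    masks survive smoothing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if na_policy not in ("propagate", "ignore"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    if callable(statistic):
        reducer = statistic
        custom = True
    else:
        try:
            prop, ign = _FOCAL_STATS[statistic]
        except KeyError:
            raise ValueError(
                f"unknown statistic {statistic!r}; have {sorted(_FOCAL_STATS)} or a callable"
            ) from None
        reducer = prop if na_policy == "propagate" else ign
        custom = False
    if window == 1 and not custom:
        return input.with_values(input.values.copy())

    half = window // 2
    out = np.empty_like(input.values)
    for b in range(input.n_bands):
        padded = np.pad(input.values[b], half, mode="constant", constant_values=np.nan)
        win = sliding_window_view(padded, (window, window)).reshape(
            input.n_rows, input.n_cols, -1
        )
        if custom:
            band = np.empty((input.n_rows, input.n_cols))
            for i in range(input.n_rows):
                for j in range(input.n_cols):
                    sample = win[i, j]
                    if na_policy == "ignore":
                        sample = sample[np.isfinite(sample)]
                        band[i, j] = reducer(sample) if sample.size else np.nan
                    else:
                        band[i, j] = np.nan if np.any(~np.isfinite(sample)) else reducer(sample)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                band = reducer(win, axis=-1)
        band[~np.isfinite(input.values[b])] = np.nan
        out[b] = band
    return input.with_values(out)


def edges(
    input: GridRaster, buffer_cells: int, treat_boundary_as_nodata: bool = False
) -> GridRaster:
    """Grow NoData regions by ``buffer_cells`` (Chebyshev/queen distance).

    Each band is buffered independently.  With
    ``treat_boundary_as_nodata=True`` the raster boundary also seeds the
    buffer, removing a frame of cells.
    """
    if buffer_cells < 1:
        raise ValueError(f"buffer_cells must be >= 1, got {buffer_cells}")
    size = 2 * buffer_cells + 1
    structure = np.ones((size, size), dtype=bool)
    out = input.values.copy()
    for b in range(input.n_bands):
        missing = ~np.isfinite(input.values[b])
        if treat_boundary_as_nodata:
            padded = np.pad(missing, buffer_cells, mode="constant", constant_values=True)
            grown = ndimage.binary_dilation(padded, structure=structure)
            grown = grown[buffer_cells:-buffer_cells, buffer_cells:-buffer_cells]
        else:
            grown = ndimage.binary_dilation(missing, structure=structure)
        out[b][grown] = np.nan
    return input.with_values(out)


def tile(input: GridRaster, n_row_tiles: int, n_col_tiles: int) -> list[GridRaster]:
    """Split a raster into a row-major list of disjoint covering tiles.

    Each tile carries a correct geotransform; :func:`mosaic` reassembles the
    original bit-for-bit.
    """
    if n_row_tiles < 1 or n_col_tiles < 1:
        raise ValueError("tile counts must be >= 1")
    if n_row_tiles > input.n_rows or n_col_tiles > input.n_cols:
        raise ValueError(
            f"tile counts ({n_row_tiles}x{n_col_tiles}) exceed raster size "
            f"({input.n_rows}x{input.n_cols})"
        )
    row_edges = np.linspace(0, input.n_rows, n_row_tiles + 1).astype(int)
    col_edges = np.linspace(0, input.n_cols, n_col_tiles + 1).astype(int)
    tiles = []
    for i in range(n_row_tiles):
        for j in range(n_col_tiles):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            tiles.append(
                GridRaster(
                    values=input.values[:, r0:r1, c0:c1].copy(),
                    band_names=list(input.band_names),
                    origin_x=input.origin_x + c0 * input.cell_size_x,
                    origin_y=input.origin_y - r0 * input.cell_size_y,
                    cell_size_x=input.cell_size_x,
                    cell_size_y=input.cell_size_y,
                    crs_id=input.crs_id,
                    nodata=input.nodata,
                )
            )
    return tiles


def mosaic(tiles: Sequence[GridRaster]) -> GridRaster:
    """Reassemble tiles produced by :func:`tile` into one raster."""
    if not tiles:
        raise ValueError("no tiles to mosaic")
    csx = tiles[0].cell_size_x
    csy = tiles[0].cell_size_y
    ox = min(t.origin_x for t in tiles)
    oy = max(t.origin_y for t in tiles)
    n_rows = max(
        int(np.rint((oy - t.origin_y) / csy)) + t.n_rows for t in tiles
    )
    n_cols = max(
        int(np.rint((t.origin_x - ox) / csx)) + t.n_cols for t in tiles
    )
    out = np.full((tiles[0].n_bands, n_rows, n_cols), np.nan)
    for t in tiles:
        r0 = int(np.rint((oy - t.origin_y) / csy))
        c0 = int(np.rint((t.origin_x - ox) / csx))
        out[:, r0 : r0 + t.n_rows, c0 : c0 + t.n_cols] = t.values
    return GridRaster(
        values=out,
        band_names=list(tiles[0].band_names),
        origin_x=ox,
        origin_y=oy,
        cell_size_x=csx,
        cell_size_y=csy,
        crs_id=tiles[0].crs_id,
        nodata=tiles[0].nodata,
    )
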