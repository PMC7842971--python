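"""GeoTIFF read/write for :class:`~forestknn.grid.GridRaster`.

Rasters are stored as planar multi-sample TIFFs carrying the GeoTIFF
ModelPixelScale and ModelTiepoint tags, the GDAL NoData ASCII tag, and a
JSON ImageDescription with the band names and CRS identifier.  This keeps
files readable by GDAL-based tools while needing only ``tifffile``.

Only north-up, same-CRS workflows are supported: the CRS is carried as an
opaque identifier (e.g. ``"EPSG:32610"``), not interpreted.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile

from .grid import GridRaster

__all__ = ["read_geotiff", "write_geotiff"]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(raster: GridRaster, path: str | os.PathLike, dtype=np.float32) -> None:
    """Write a raster to GeoTIFF; NaN cells become the nodata sentinel.

    If ``raster.nodata`` is None, NaN itself is declared as the nodata value
    (valid for float rasters and understood by GDAL).
    """
    arr = np.asarray(raster.values, dtype=dtype)
    nodata = raster.nodata
    if nodata is not None and not np.isnan(nodata):
        arr = np.where(np.isnan(arr), dtype(nodata), arr)
        nodata_str = repr(float(nodata))
    else:
        nodata_str = "nan"
    desc = json.dumps({"band_names": raster.band_names, "crs_id": raster.crs_id})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(raster.cell_size_x), float(raster.cell_size_y), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(raster.origin_x), float(raster.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    kwargs = {"photometric": "minisblack", "description": desc, "extratags": extratags}
    if arr.shape[0] == 1:
        arr = arr[0]  # single band: plain 2-D page
    else:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(os.fspath(path), arr, **kwargs)


def read_geotiff(path: str | os.PathLike) -> GridRaster:
    """Read a GeoTIFF written by :func:`write_geotiff` (or similar).

    Falls back to a unit geotransform when geo tags are absent, so plain
    TIFFs remain loadable for testing.
    """
    with tifffile.TiffFile(os.fspath(path)) as tf:
        page = tf.pages[0]
        arr = tf.asarray().astype(float)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        elif arr.ndim == 3 and page.planarconfig != 2:
            # contiguous samples come back (rows, cols, bands)
            arr = np.moveaxis(arr, -1, 0)

        tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        csx, csy = (tag.value[0], tag.value[1]) if tag is not None else (1.0, 1.0)
        tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        ox, oy = (tag.value[3], tag.value[4]) if tag is not None else (0.0, float(arr.shape[1]))
        tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = None
        if tag is not None:
            try:
                nodata = float(str(tag.value).strip())
            except ValueError:
                nodata = None

        band_names = [f"band_{i + 1}" for i in range(arr.shape[0])]
        crs_id = ""
        if page.description:
            try:
                meta = json.loads(page.description)
                band_names = list(meta.get("band_names", band_names))
                crs_id = str(meta.get("crs_id", ""))
            except (json.JSONDecodeError, TypeError):
                pass

    return GridRaster(
        values=arr,
        band_names=band_names,
        origin_x=float(ox),
        origin_y=float(oy),
        cell_size_x=float(csx),
        cell_size_y=float(csy),
        crs_id=crs_id,
        nodata=nodata,
    )
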