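"""Spectral indices from multispectral rasters or extracted point values.

Supported out of the box: NDVI, NBR and the Tasseled Cap components
(brightness TCB, greenness TCG, wetness TCW).  Tasseled Cap is a linear
transform of the six reflective bands; the coefficient table is versioned
data keyed by sensor tag so its provenance is explicit.  Inputs are assumed
to be surface reflectance on a [0, 1] scale (Tasseled Cap coefficients are
scale-sensitive; a uniform integer scaling only rescales the components).

The same computation runs on rasters (bands) and on point tables
(columns): a :class:`BandMap` names which band index / column holds each
semantic role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .grid import GridRaster
from .points import SamplePoints

__all__ = ["BandMap", "calc_indices", "register_index", "TASSELED_CAP_COEFFICIENTS"]

BAND_ROLES = ("blue", "green", "red", "nir", "swir1", "swir2")
_TC_ROLES = BAND_ROLES  # all six reflective bands, in this order

# Landsat-4/5 TM Tasseled Cap coefficients for reflectance data
# (Crist 1985, "A TM Tasseled Cap equivalent transformation for reflectance
# factor data"), band order blue, green, red, nir, swir1, swir2.
TASSELED_CAP_COEFFICIENTS: dict[str, dict[str, tuple[float, ...]]] = {
    "landsat5tm": {
        "TCB": (0.2043, 0.4158, 0.5524, 0.5741, 0.3124, 0.2303),
        "TCG": (-0.1603, -0.2819, -0.4934, 0.7940, -0.0002, -0.1446),
        "TCW": (0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109),
    },
}


@dataclass(frozen=True)
class BandMap:
    """Maps semantic band roles to band indices (raster) or column names
    (point table); ``sensor`` selects the Tasseled Cap coefficient set."""

    bands: Mapping[str, Union[int, str]]
    sensor: str = "landsat5tm"

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(BAND_ROLES)
        if unknown:
            raise ValueError(f"unknown band roles {sorted(unknown)}; valid: {BAND_ROLES}")
        refs = list(self.bands.values())
        if len(set(refs)) != len(refs):
            raise ValueError("band roles must map to distinct bands")

    def require(self, roles: Sequence[str]) -> None:
        missing = [r for r in roles if r not in self.bands]
        if missing:
            raise ValueError(f"band map lacks roles {missing} (has {sorted(self.bands)})")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.asarray(out, dtype=float)
    out[np.asarray(den) == 0] = np.nan
    return out


def _ndvi(b: dict) -> np.ndarray:
    return _safe_ratio(b["nir"] - b["red"], b["nir"] + b["red"])


def _nbr(b: dict) -> np.ndarray:
    return _safe_ratio(b["nir"] - b["swir2"], b["nir"] + b["swir2"])


def _tasseled_cap(component: str):
    def fn(b: dict, sensor: str) -> np.ndarray:
        try:
            coef = TASSELED_CAP_COEFFICIENTS[sensor][component]
        except KeyError:
            raise ValueError(
                f"no Tasseled Cap coefficients for sensor {sensor!r}; "
                f"known: {sorted(TASSELED_CAP_COEFFICIENTS)}"
            ) from None
        return sum(c * b[role] for c, role in zip(coef, _TC_ROLES))

    return fn


# registry: name -> (required roles, fn(bands_dict [, sensor]) -> array, needs_sensor)
_INDEX_REGISTRY: dict[str, tuple[tuple[str, ...], Callable, bool]] = {
    "NDVI": (("red", "nir"), _ndvi, False),
    "NBR": (("nir", "swir2"), _nbr, False),
    "TCB": (_TC_ROLES, _tasseled_cap("TCB"), True),
    "TCG": (_TC_ROLES, _tasseled_cap("TCG"), True),
    "TCW": (_TC_ROLES, _tasseled_cap("TCW"), True),
}


def register_index(name: str, roles: Sequence[str], fn: Callable[[dict], np.ndarray]) -> None:
    """Add a named index formula (fn receives a role -> array dict)."""
    if name in _INDEX_REGISTRY:
        raise ValueError(f"index {name!r} is already registered")
    _INDEX_REGISTRY[name] = (tuple(roles), fn, False)


def _resolve_raster_band(raster: GridRaster, ref: Union[int, str]) -> np.ndarray:
    if isinstance(ref, str):
        return raster.band(ref)
    if not 0 <= ref < raster.n_bands:
        raise ValueError(f"band index {ref} out of range for {raster.n_bands} bands")
    return raster.values[ref]


def calc_indices(
    input: Union[GridRaster, SamplePoints],
    indices: Sequence[str],
    band_map: BandMap,
) -> Union[GridRaster, SamplePoints]:
    """Compute spectral indices; returns the same container kind as the input
    with one band/column per requested index, named after the index."""
    if not indices:
        raise ValueError("no indices requested")
    for name in indices:
        if name not in _INDEX_REGISTRY:
            raise ValueError(f"unknown index {name!r}; known: {sorted(_INDEX_REGISTRY)}")
        roles, _, _ = _INDEX_REGISTRY[name]
        band_map.require(roles)

    if isinstance(input, GridRaster):
        bands = {role: _resolve_raster_band(input, ref) for role, ref in band_map.bands.items()}
        out = []
        for name in indices:
            roles, fn, needs_sensor = _INDEX_REGISTRY[name]
            arr = fn(bands, band_map.sensor) if needs_sensor else fn(bands)
            out.append(arr)
        return input.with_values(np.stack(out), band_names=list(indices))

    if isinstance(input, SamplePoints):
        cols = {}
        for role, ref in band_map.bands.items():
            if not isinstance(ref, str):
                raise ValueError("point inputs need column-name band references")
            if ref not in input.data.columns:
                raise ValueError(f"column {ref!r} missing from points")
            cols[role] = input.data[ref].to_numpy(dtype=float)
        frame = {}
        for name in indices:
            roles, fn, needs_sensor = _INDEX_REGISTRY[name]
            frame[name] = fn(cols, band_map.sensor) if needs_sensor else fn(cols)
        return input.with_columns(pd.DataFrame(frame))

    raise TypeError(f"unsupported input type {type(input).__name__}")
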