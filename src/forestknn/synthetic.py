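"""Seeded synthetic scenes for end-to-end testing without external data.

A scene emulates the input stack of a forest-structure imputation study on
one shared grid: an annual series of six-band surface-reflectance
composites, terrain (DEM and slope), a forested-area mask, and two
response rasters (a canopy-height percentile ``elev_p95`` in metres and a
canopy ``cover`` percentage) tied to the predictors by a known link.

The landscape is built from spatially correlated random fields.  Canopy
structure is driven by a *stand-type* pattern — smooth patches thresholded
into discrete classes (young/open vs mature/closed stands) plus bounded
within-stand variation — so the response distribution is multimodal, as in
managed forests where distinct stand conditions dominate the variance.
Yearly reflectance encodes a per-pixel NDVI baseline and linear trend; the
noiseless NDVI median over the (odd-length) year range equals the baseline
and the noiseless Theil–Sen slope equals the trend, which makes the
temporal-metric stages exactly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridRaster, GridSpec
from .temporal import RasterTimeSeries

__all__ = ["SceneParams", "Scene", "make_scene", "make_reference_strips"]

_BAND_NAMES = ["blue", "green", "red", "nir", "swir1", "swir2"]


@dataclass(frozen=True)
class SceneParams:
    """Synthetic-scene configuration.

    Defaults mirror a desk-scale version of a typical study setup: a
    30 m grid, a 25-year annual series (1984-2008), and response noise at
    10% of the noiseless response range.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 30.0
    origin_x: float = 500000.0
    origin_y: float = 5600000.0
    crs_id: str = "EPSG:32610"
    years: tuple[int, ...] = tuple(range(1984, 2009))
    corr_length: float = 8.0  # cells; spatial autocorrelation of the fields
    n_stand_types: int = 2  # discrete canopy classes (young/open, mature/closed)
    trend_range: float = 0.004  # max |NDVI slope| per year
    reflectance_noise_sd: float = 0.01  # per-band, per-year
    noise_sd_frac: float = 0.10  # response noise sd as fraction of clean range
    mask_fraction: float = 0.05  # non-forested (NoData) share of the scene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("scene must be at least 4x4 cells")
        if len(self.years) < 2:
            raise ValueError("need at least two years")
        if self.noise_sd_frac < 0 or self.reflectance_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not (0 <= self.mask_fraction <= 1):
            raise ValueError("mask_fraction must be in [0, 1]")
        if self.n_stand_types < 1:
            raise ValueError("need at least one stand type")


@dataclass
class Scene:
    """A generated scene plus the ground truth behind it."""

    series: RasterTimeSeries
    dem: GridRaster
    slope: GridRaster
    mask: GridRaster
    responses: GridRaster
    truth: dict


# link coefficients: response = intercept + a*ndvi_c + b*dem_c + c*ndvi_c*dem_c
# with ndvi_c = ndvi_median - 0.575 and dem_c = (dem - 600)/150
_LINK = {
    "elev_p95": {"intercept": 20.0, "ndvi": 45.0, "dem": 1.5, "interaction": 3.0},
    "cover": {"intercept": 60.0, "ndvi": 55.0, "dem": 2.0, "interaction": 4.0},
}
_NDVI_CENTER = 0.575
_DEM_BASE = 600.0
_DEM_SCALE = 150.0
_NDVI_LEVEL_LO = 0.30
_NDVI_LEVEL_HI = 0.85


def _smooth_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Standardized spatially correlated field (mean 0, sd 1)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_length, mode="reflect")
    return (f - f.mean()) / f.std()


def _link_response(name: str, ndvi_med: np.ndarray, dem: np.ndarray) -> np.ndarray:
    c = _LINK[name]
    ndvi_c = ndvi_med - _NDVI_CENTER
    dem_c = (dem - _DEM_BASE) / _DEM_SCALE
    return (
        c["intercept"]
        + c["ndvi"] * ndvi_c
        + c["dem"] * dem_c
        + c["interaction"] * ndvi_c * dem_c
    )


def make_scene(params: SceneParams = SceneParams()) -> Scene:
    """Generate a full scene; identical parameters and seed give
    bit-identical outputs."""
    rng = np.random.default_rng(params.seed)
    shape = (params.n_rows, params.n_cols)
    spec = GridSpec(
        origin_x=params.origin_x,
        origin_y=params.origin_y,
        cell_size_x=params.cell_size,
        cell_size_y=params.cell_size,
        n_rows=params.n_rows,
        n_cols=params.n_cols,
        crs_id=params.crs_id,
    )

    def as_raster(arr, names):
        return GridRaster.from_spec(np.asarray(arr), names, spec)

    # --- stand structure: discrete classes + bounded within-stand variation
    u_stand = _smooth_field(rng, shape, params.corr_length)
    k = params.n_stand_types
    if k == 1:
        stand_class = np.zeros(shape, dtype=int)
    else:
        qs = np.quantile(u_stand, np.linspace(0, 1, k + 1)[1:-1])
        stand_class = np.digitize(u_stand, qs)
    if k == 1:
        levels = np.array([(_NDVI_LEVEL_LO + _NDVI_LEVEL_HI) / 2])
    else:
        levels = np.linspace(_NDVI_LEVEL_LO, _NDVI_LEVEL_HI, k)
    within = 0.03 * np.tanh(_smooth_field(rng, shape, params.corr_length))
    ndvi_base = np.clip(levels[stand_class] + within, 0.02, 0.98)

    # --- NDVI trend (per-year slope), bounded by trend_range
    trend = params.trend_range * np.tanh(_smooth_field(rng, shape, params.corr_length))

    # --- terrain
    dem_vals = _DEM_BASE + _DEM_SCALE * np.tanh(_smooth_field(rng, shape, params.corr_length))
    dy, dx = np.gradient(dem_vals, params.cell_size)
    slope_vals = np.degrees(np.arctan(np.hypot(dx, dy)))
    dem = as_raster(dem_vals, ["DEM"])
    slope = as_raster(slope_vals, ["DEM_slope"])

    # --- static background reflectance fields
    bg = _smooth_field(rng, shape, params.corr_length)
    swir_base = np.clip(0.25 + 0.05 * bg, 0.02, 0.6)

    years = np.asarray(params.years, dtype=float)
    mid_year = float(np.median(years))
    layers = []
    for year in params.years:
        ndvi_t = np.clip(ndvi_base + trend * (year - mid_year), -0.99, 0.99)
        nir = 0.25 * (1.0 + ndvi_t)
        red = 0.25 * (1.0 - ndvi_t)
        green = 0.06 + 0.5 * red
        blue = 0.04 + 0.4 * red
        swir1 = swir_base
        swir2 = 0.8 * swir_base
        bands = np.stack([blue, green, red, nir, swir1, swir2])
        if params.reflectance_noise_sd > 0:
            bands = bands + rng.normal(0.0, params.reflectance_noise_sd, bands.shape)
        bands = np.clip(bands, 0.0, 1.0)
        layers.append(as_raster(bands, _BAND_NAMES))
    series = RasterTimeSeries(layers=layers, years=list(params.years))

    # --- forested mask (1 = forested, NoData elsewhere)
    u_mask = _smooth_field(rng, shape, params.corr_length / 2)
    if params.mask_fraction >= 1.0:
        forested = np.zeros(shape, dtype=bool)
    elif params.mask_fraction <= 0.0:
        forested = np.ones(shape, dtype=bool)
    else:
        forested = u_mask > np.quantile(u_mask, params.mask_fraction)
    mask_vals = np.where(forested, 1.0, np.nan)
    mask = as_raster(mask_vals, ["forested"])

    # --- responses = link(true NDVI median, DEM) + noise, masked to forest
    clean = {name: _link_response(name, ndvi_base, dem_vals) for name in _LINK}
    noise_sd = {
        name: params.noise_sd_frac * float(arr.max() - arr.min())
        for name, arr in clean.items()
    }
    resp_bands = []
    for name in _LINK:
        noisy = clean[name] + (
            rng.normal(0.0, noise_sd[name], shape) if noise_sd[name] > 0 else 0.0
        )
        noisy = np.where(forested, noisy, np.nan)
        resp_bands.append(noisy)
    responses = as_raster(np.stack(resp_bands), list(_LINK))

    truth = {
        "link": _LINK,
        "ndvi_center": _NDVI_CENTER,
        "dem_base": _DEM_BASE,
        "dem_scale": _DEM_SCALE,
        "ndvi_median": as_raster(ndvi_base, ["ndvi_median_true"]),
        "ndvi_slope": as_raster(trend, ["ndvi_slope_true"]),
        "responses_clean": as_raster(
            np.stack([clean[n] for n in _LINK]), list(_LINK)
        ),
        "noise_sd": noise_sd,
        "mid_year": mid_year,
    }
    return Scene(series=series, dem=dem, slope=slope, mask=mask, responses=responses, truth=truth)


def make_reference_strips(
    responses: GridRaster, n_strips: int, strip_width_cells: int
) -> GridRaster:
    """Keep responses only inside vertical strips, NoData elsewhere.

    Emulates discontinuous acquisition blocks: the retained strips act as
    the reference area and their complement as the imputation target.
    ``n_strips`` strips of ``strip_width_cells`` columns are centered in
    equal-width segments of the raster.
    """
    if n_strips < 0 or strip_width_cells < 1:
        raise ValueError("need n_strips >= 0 and strip_width_cells >= 1")
    n_cols = responses.n_cols
    if n_strips * strip_width_cells > n_cols:
        raise ValueError(
            f"{n_strips} strips of {strip_width_cells} cells exceed {n_cols} columns"
        )
    keep = np.zeros(n_cols, dtype=bool)
    if n_strips > 0:
        seg = n_cols / n_strips
        for i in range(n_strips):
            start = int(round(i * seg + (seg - strip_width_cells) / 2))
            keep[start : start + strip_width_cells] = True
    out = responses.values.copy()
    out[:, :, ~keep] = np.nan
    return responses.with_values(out)
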