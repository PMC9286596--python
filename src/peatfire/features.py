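"""Predictor-layer construction for the susceptibility models.

Covers land-cover regrouping and binary expansion, the forest clearance
index, vegetation-index preparation (gap filling, ET:PET ratio, optional
reference-area normalization), precipitation downscaling, distance-to-
infrastructure rasters, terrain derivatives, the ONI layer, seasonal
aggregation, and min-max normalization pooled across training years.

Drought-index (SPEI) fitting lives in :mod:`peatfire.spei`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import convolve
from shapely.geometry.base import BaseGeometry

from .exceptions import (
    AlignmentError,
    ExtentError,
    GeometryError,
    MappingError,
    NormalizationError,
)
from .grids import GridSpec, check_same_grid

# The reduced 8-class land-cover scheme. Values are raster codes; 0 is nodata.
LC_CLASSES = {
    "dry_forest": 1,
    "swamp_forest": 2,
    "swamp_scrub": 3,
    "scrub_bare": 4,
    "riceland": 5,
    "plantation": 6,
    "settlement": 7,
    "water_cloud": 8,
}
LC_NODATA = 0
DEFAULT_FOREST_CLASSES = frozenset({"dry_forest", "swamp_forest"})

PRE_FIRE_MONTHS = (5, 6, 7)   # May-July
FIRE_MONTHS = (8, 9, 10)      # August-October


@dataclass(frozen=True)
class LandCoverMap:
    """Categorical land-cover raster over the reduced 8-class scheme."""

    grid: GridSpec
    classes: np.ndarray  # uint8 codes, LC_NODATA where missing
    map_year: int

    def __post_init__(self) -> None:
        if self.classes.shape != self.grid.shape:
            raise AlignmentError("land-cover raster shape does not match grid")
        valid = self.classes[self.classes != LC_NODATA]
        codes = set(LC_CLASSES.values())
        bad = set(np.unique(valid)) - codes
        if bad:
            raise MappingError(f"raster holds non-scheme class codes {sorted(bad)}")


@dataclass(frozen=True)
class ClearanceIndexRaster:
    """Signed time-since-clearance index in [-10, 10]; 0 = no recorded change."""

    grid: GridSpec
    values: np.ndarray  # int raster
    as_of_map_year: int


@dataclass(frozen=True)
class NormalizationParams:
    """Pooled min/max of one predictor across all training years."""

    name: str
    vmin: float
    vmax: float


@dataclass
class SeasonalFeatureStack:
    """Co-registered predictor layers for one year, keyed by feature name."""

    grid: GridSpec
    year: int
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise AlignmentError(f"layer {name!r} shape does not match grid")


# ---------------------------------------------------------------------------
# Land cover
# ---------------------------------------------------------------------------

def regroup_landcover(raw: np.ndarray, mapping: dict[int, str], grid: GridSpec,
                      map_year: int, nodata: int = LC_NODATA) -> LandCoverMap:
    """Relabel a raw categorical raster onto the 8-class scheme.

    ``mapping`` sends every raw class code to one of the 8 class names;
    an unmapped code present in the raster is an error (never silently
    dropped), since the regrouping table is study-specific configuration.
    """
    raw = np.asarray(raw)
    out = np.full(raw.shape, LC_NODATA, dtype=np.uint8)
    present = set(np.unique(raw)) - {nodata}
    unmapped = present - set(mapping)
    if unmapped:
        raise MappingError(f"raw classes {sorted(unmapped)} missing from mapping")
    for code, name in mapping.items():
        if name not in LC_CLASSES:
            raise MappingError(f"mapping targets unknown class {name!r}")
        out[raw == code] = LC_CLASSES[name]
    return LandCoverMap(grid=grid, classes=out, map_year=map_year)


def binary_expand(lcmap: LandCoverMap) -> dict[str, np.ndarray]:
    """One 0/1 float raster per class (NaN where the input is nodata)."""
    out = {}
    nodata = lcmap.classes == LC_NODATA
    for name, code in LC_CLASSES.items():
        layer = (lcmap.classes == code).astype(float)
        layer[nodata] = np.nan
        out[f"lc_{name}"] = layer
    return out


def forest_clearance_index(maps: list[LandCoverMap], target_map_year: int,
                           forest_classes: frozenset[str] = DEFAULT_FOREST_CLASSES,
                           ) -> ClearanceIndexRaster:
    """Track time since forest clearing or regrowth across map iterations.

    Each land-cover map is binarized to forest/non-forest. A pixel flipping
    forest->non-forest at a map iteration is assigned -10 (+10 for the
    reverse); at every subsequent iteration where it keeps its new state
    the index moves one step toward zero. A fresh transition overwrites the
    running value with a new +/-10. Pixels with no transition on record
    stay at 0. Decay counts map iterations, not calendar years, so the
    irregular map-date spacing is reflected as-is.
    """
    years = [m.map_year for m in maps]
    if years != sorted(years) or len(set(years)) != len(years):
        raise ValueError("land-cover maps must have strictly increasing map_years")
    used = [m for m in maps if m.map_year <= target_map_year]
    if len(used) < 2:
        raise ValueError("need at least two maps at or before the target year")
    check_same_grid(*[m.grid for m in used])

    codes = {LC_CLASSES[c] for c in forest_classes}
    forest = [np.isin(m.classes, list(codes)) for m in used]

    index = np.zeros(used[0].grid.shape, dtype=np.int16)
    prev = forest[0]
    for cur in forest[1:]:
        index -= np.sign(index).astype(np.int16)  # decay toward 0
        loss = prev & ~cur
        gain = ~prev & cur
        index[loss] = -10
        index[gain] = 10
        prev = cur
    return ClearanceIndexRaster(grid=used[0].grid, values=index,
                                as_of_map_year=used[-1].map_year)


# ---------------------------------------------------------------------------
# Vegetation-index preparation
# ---------------------------------------------------------------------------

_WINDOW5 = np.ones((5, 5))


def gap_fill(raster: np.ndarray) -> np.ndarray:
    """Infill missing pixels with the mean of their 5x5 neighbourhood.

    Only NaN pixels change; a pixel whose whole (in-bounds) window is
    missing stays NaN. At edges the window is truncated to the raster.
    """
    x = np.asarray(raster, dtype=float)
    valid = np.isfinite(x)
    sums = convolve(np.where(valid, x, 0.0), _WINDOW5, mode="constant", cval=0.0)
    counts = convolve(valid.astype(float), _WINDOW5, mode="constant", cval=0.0)
    out = x.copy()
    fillable = ~valid & (counts > 0)
    out[fillable] = sums[fillable] / counts[fillable]
    return out


def et_pet_ratio(et: np.ndarray, pet: np.ndarray) -> np.ndarray:
    """Pixelwise ET/PET, a soil-moisture-deficiency proxy; NaN where PET <= 0."""
    et = np.asarray(et, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if et.shape != pet.shape:
        raise AlignmentError("ET and PET rasters differ in shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = et / pet
    out[~(pet > 0)] = np.nan
    return out


def normalize_by_reference(raster: np.ndarray, reference_polygon: BaseGeometry,
                           grid: GridSpec) -> np.ndarray:
    """Express a layer as the ratio to its mean over a reference area.

    The reference is typically intact primary forest, so values read as
    "state relative to an assumed healthy norm".
    """
    x = np.asarray(raster, dtype=float)
    xm, ym = grid.center_mesh()
    inside = shapely.contains_xy(reference_polygon, xm.ravel(), ym.ravel())
    inside = inside.reshape(grid.shape)
    ref = x[inside]
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise NormalizationError("reference polygon covers no valid pixels")
    mean = ref.mean()
    if mean == 0:
        raise NormalizationError("reference mean is zero")
    return x / mean


def interpolate_precip(coarse: np.ndarray, coarse_grid: GridSpec,
                       fine_grid: GridSpec) -> np.ndarray:
    """Bilinearly interpolate a coarse raster onto a finer grid.

    Interpolation is between cell-centre values, so a fine centre that
    coincides with a coarse centre reproduces it exactly. Fine centres in
    the half-cell margin inside the coarse extent are clamped to the
    coarse-centre hull (edge padding); a fine grid extending beyond the
    coarse raster extent itself is an error.
    """
    fb, cb = fine_grid.bounds, coarse_grid.bounds
    if fb[0] < cb[0] or fb[1] < cb[1] or fb[2] > cb[2] or fb[3] > cb[3]:
        raise ExtentError("fine grid extends beyond the coarse raster extent")
    ys = coarse_grid.y_centers()[::-1]  # ascending for the interpolator
    xs = coarse_grid.x_centers()
    interp = RegularGridInterpolator(
        (ys, xs), np.asarray(coarse, dtype=float)[::-1, :], method="linear",
        bounds_error=False, fill_value=None)
    xm, ym = fine_grid.center_mesh()
    xq = np.clip(xm.ravel(), xs[0], xs[-1])
    yq = np.clip(ym.ravel(), ys[0], ys[-1])
    return interp(np.column_stack([yq, xq])).reshape(fine_grid.shape)


# ---------------------------------------------------------------------------
# Distance, terrain, ONI
# ---------------------------------------------------------------------------

def distance_raster(features, grid: GridSpec) -> np.ndarray:
    """Euclidean distance (m) from each cell centre to the nearest feature."""
    geoms = list(features)
    if not geoms:
        raise GeometryError("empty feature set")
    union = shapely.union_all(geoms)
    xm, ym = grid.center_mesh()
    pts = shapely.points(xm.ravel(), ym.ravel())
    return shapely.distance(pts, union).reshape(grid.shape)


def terrain_derivatives(elevation: np.ndarray, grid: GridSpec,
                        flat_threshold: float = 1e-6,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees clockwise from north).

    Gradients are 4-neighbour central differences (one-sided at edges).
    Aspect is the downslope azimuth; cells with gradient magnitude below
    ``flat_threshold`` get NaN aspect.
    """
    z = np.asarray(elevation, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation raster must be at least 3x3")
    # row 0 is north: +row is south, so the northward gradient is -d/drow
    dz_drow, dz_dcol = np.gradient(z, grid.cell_size)
    gx = dz_dcol          # east component of the gradient
    gy = -dz_drow         # north component
    mag = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(mag))
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0  # downslope azimuth
    aspect[mag < flat_threshold] = np.nan
    return slope, aspect


def oni_layer(oni_by_year: dict[int, float], year: int, grid: GridSpec) -> np.ndarray:
    """Spatially constant raster holding the year's early-fire-season ONI."""
    if year not in oni_by_year:
        raise KeyError(f"no ONI value for year {year}")
    return np.full(grid.shape, float(oni_by_year[year]))


# ---------------------------------------------------------------------------
# Seasonal aggregation
# ---------------------------------------------------------------------------

def seasonal_aggregate(monthly: dict[int, np.ndarray],
                       months: tuple[int, ...]) -> np.ndarray:
    """Pixelwise mean over the named months (e.g. May-Jul or Aug-Oct)."""
    missing = [m for m in months if m not in monthly]
    if missing:
        raise ValueError(f"missing months {missing} for seasonal aggregation")
    return np.mean([np.asarray(monthly[m], dtype=float) for m in months], axis=0)


def delta_aug_prefs(monthly: dict[int, np.ndarray],
                    pre_season_mean: np.ndarray) -> np.ndarray:
    """August value minus the pre-fire-season (May-Jul) mean."""
    if 8 not in monthly:
        raise ValueError("missing months [8] for August delta")
    return np.asarray(monthly[8], dtype=float) - np.asarray(pre_season_mean, dtype=float)


# ---------------------------------------------------------------------------
# Cross-year normalization
# ---------------------------------------------------------------------------

def cross_year_normalize(stacks: dict[int, dict[str, np.ndarray]],
                         on_constant: str = "error",
                         ) -> tuple[dict[int, dict[str, np.ndarray]],
                                    dict[str, NormalizationParams]]:
    """Min-max scale each variable with min/max pooled across all years.

    Vnorm = (V - Vmin) / (Vmax - Vmin) with Vmin/Vmax taken over the whole
    training record, so inter-annual differences survive scaling. Params
    are returned for reuse on held-out years, where values outside [0, 1]
    are legitimate. A constant variable is an error unless
    ``on_constant="passthrough"`` keeps it unscaled.
    """
    if not stacks:
        raise ValueError("no stacks given")
    names = sorted({n for layers in stacks.values() for n in layers})
    params: dict[str, NormalizationParams] = {}
    for name in names:
        vals = [layers[name] for layers in stacks.values() if name in layers]
        vmin = float(np.nanmin([np.nanmin(v) for v in vals]))
        vmax = float(np.nanmax([np.nanmax(v) for v in vals]))
        if vmax == vmin and on_constant != "passthrough":
            raise NormalizationError(
                f"variable {name!r} is constant (={vmin}) across all years")
        params[name] = NormalizationParams(name=name, vmin=vmin, vmax=vmax)
    normalized = {
        year: apply_normalization(layers, params) for year, layers in stacks.items()
    }
    return normalized, params


def apply_normalization(layers: dict[str, np.ndarray],
                        params: dict[str, NormalizationParams],
                        ) -> dict[str, np.ndarray]:
    out = {}
    for name, arr in layers.items():
        p = params[name]
        if p.vmax == p.vmin:
            out[name] = np.asarray(arr, dtype=float).copy()
        else:
            out[name] = (np.asarray(arr, dtype=float) - p.vmin) / (p.vmax - p.vmin)
    return out


def save_normalization(path: str | Path,
                       params: dict[str, NormalizationParams]) -> None:
    with open(path, "w") as fh:
        json.dump({n: {"vmin": p.vmin, "vmax": p.vmax} for n, p in params.items()},
                  fh, indent=1)


def load_normalization(path: str | Path) -> dict[str, NormalizationParams]:
    with open(path) as fh:
        raw = json.load(fh)
    return {n: NormalizationParams(name=n, **v) for n, v in raw.items()}
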