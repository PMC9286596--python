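"""Synthetic study region with a known fire-generation process.

Emulates the structure of the real inputs used for peatland fire
susceptibility modelling in the Ex-Mega Rice Project area — categorical
land-cover maps at irregular dates, monthly vegetation/water rasters,
coarse precipitation, vector infrastructure, and multi-year hotspot point
sets — while keeping the true drivers of fire known, so every downstream
stage can be verified against ground truth.

The fire process plants a logistic dependence on normalized drivers
(distance to settlements/canals, ONI, pre-season vegetation state): for
each cell and fire-season month, fire occurs with probability
``logistic(intercept + sum(w_i * z_i))`` where ``z_i`` are min-max
normalized drivers and the intercept is chosen so that a cell with all
drivers at mid-range burns at ``base_rate``. Burning cells emit 1 + Poisson
detections snapped to the emitting sensor's nominal grid (1 km MODIS
centres; 375 m VIIRS centres for years >= 2012), with dates inside
August-October.

Randomness is organised as one generator stream per stage, derived from
the scenario seed by fixed offsets, so regenerating one stage never
perturbs another.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from shapely.geometry import LineString, Point

from . import features as F
from .exceptions import SizingError
from .grids import GridSpec
from .records import SENSOR_RESOLUTION, VIIRS_FIRST_YEAR, HotspotRecord

_STAGE = {"landscape": 1, "series": 2, "hotspots": 3, "clouds": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE[stage]])


@dataclass
class SyntheticScenario:
    """Full parameterization of one synthetic study region.

    ``driver_weights`` are the true log-odds weights of the planted
    susceptibility function on min-max normalized drivers; ``base_rate``
    is the per-cell, per-fire-season-month burn probability at mid-range
    driver values. ``clearance_rate`` is the per-interval probability that
    a forest cell is cleared between consecutive land-cover maps.
    """

    seed: int = 0
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    map_dates: tuple[int, ...] = (1996, 2000, 2003, 2006, 2009, 2011, 2012, 2013, 2015)
    n_settlements: int = 5
    n_canals: int = 8
    n_roads: int = 6
    oni_by_year: dict[int, float] = field(default_factory=dict)
    driver_weights: dict[str, float] = field(default_factory=lambda: {
        "dist_settlements": -3.0,
        "dist_canals": -2.0,
        "oni": 1.5,
        "ndvi": -1.0,
    })
    base_rate: float = 0.03
    clearance_rate: float = 0.02
    missing_fraction: float = 0.02
    emission_mean: float = 2.0
    detection_drop_rate: float = 0.0
    precip_noise_cv: float = 0.5
    weather_start_year: int | None = None

    def __post_init__(self) -> None:
        self.years = tuple(self.years)
        if not self.years or list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be non-empty and strictly increasing")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must be in (0, 1)")
        if not all(math.isfinite(w) for w in self.driver_weights.values()):
            raise ValueError("driver_weights must be finite")
        if not self.oni_by_year:
            # Mild ENSO cycle over the study years: one strong El Nino year,
            # a La Nina dip, and near-neutral years in between.
            cycle = [1.5, -0.5, -0.2, 0.1, 0.4, -0.3, 0.8, 0.0]
            self.oni_by_year = {y: cycle[i % len(cycle)]
                                for i, y in enumerate(self.years)}

    @property
    def weather_years(self) -> tuple[int, ...]:
        """Years with generated weather: study years plus a spin-up period
        long enough for a stable drought-index reference climatology."""
        start = (self.weather_start_year if self.weather_start_year is not None
                 else min(self.years) - 14)
        return tuple(range(start, max(self.years) + 1))

    # Deterministic pseudo-ENSO cycle for spin-up weather years that have
    # no explicit ONI entry, so the drought-index reference climatology
    # sees realistic inter-annual forcing.
    _ONI_SPINUP = (0.5, -0.7, 0.2, 1.2, -0.3, 0.0, 0.9, -0.5, 0.1, 0.6,
                   -0.8, 0.3, 1.6, -0.2, 0.4)

    def oni_for(self, year: int) -> float:
        if year in self.oni_by_year:
            return self.oni_by_year[year]
        return self._ONI_SPINUP[year % len(self._ONI_SPINUP)]


@dataclass
class LandscapeBundle:
    grid: GridSpec
    land_cover: dict[int, F.LandCoverMap]        # keyed by map year
    elevation: np.ndarray
    peat_depth: np.ndarray
    settlements: list[Point]
    canals: list[LineString]
    roads: list[LineString]

    def landcover_for_year(self, year: int) -> F.LandCoverMap:
        """Most recent land-cover map at or before ``year``."""
        dates = [d for d in self.land_cover if d <= year]
        if not dates:
            raise KeyError(f"no land-cover map at or before {year}")
        return self.land_cover[max(dates)]


@dataclass
class MonthlySeries:
    """Monthly raster time series; precipitation on a coarser grid."""

    grid: GridSpec
    precip_grid: GridSpec
    precip: dict[tuple[int, int], np.ndarray]
    ndvi: dict[tuple[int, int], np.ndarray]
    evi: dict[tuple[int, int], np.ndarray]
    et: dict[tuple[int, int], np.ndarray]
    pet: dict[tuple[int, int], np.ndarray]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _random_chord(rng: np.random.Generator, bounds) -> LineString:
    """A straight line crossing the region, entering/leaving at the edges."""
    minx, miny, maxx, maxy = bounds
    # pick two points on different edges
    edges = rng.choice(4, size=2, replace=False)
    pts = []
    for e in edges:
        t = rng.uniform()
        pts.append({
            0: (minx + t * (maxx - minx), miny),
            1: (minx + t * (maxx - minx), maxy),
            2: (minx, miny + t * (maxy - miny)),
            3: (maxx, miny + t * (maxy - miny)),
        }[int(e)])
    return LineString(pts)


def generate_landscape(scenario: SyntheticScenario, grid: GridSpec) -> LandscapeBundle:
    """Static rasters, vector infrastructure, and the land-cover map series.

    Land cover starts as a mosaic of swamp forest over deep peat, dry
    forest on shallower ground, scrub and cultivation patches, and water
    in the lowest-lying cells; settlement cells surround the settlement
    points. Between consecutive map dates each forest cell is cleared to
    swamp scrubland with probability ``clearance_rate`` — forest extent
    never grows, so the clearance index exercises only the loss branch on
    default scenarios.
    """
    if grid.n_rows < 50 or grid.n_cols < 50:
        raise SizingError("synthetic landscape needs a grid of at least 50x50 cells")
    n_feats = scenario.n_settlements + scenario.n_canals + scenario.n_roads
    if n_feats > grid.n_rows * grid.n_cols // 10:
        raise SizingError("grid too small for the requested feature counts")
    rng = _rng(scenario.seed, "landscape")
    shape = grid.shape

    elevation = 8.0 + 4.0 * gaussian_filter(rng.normal(size=shape), sigma=6) \
        + 0.002 * grid.cell_size * np.linspace(0, 1, grid.n_cols)[None, :]
    peat_depth = np.clip(3.0 + 3.0 * gaussian_filter(rng.normal(size=shape), sigma=8),
                         0.0, 12.0)

    minx, miny, maxx, maxy = grid.bounds
    pad = 2 * grid.cell_size
    settlements = [Point(rng.uniform(minx + pad, maxx - pad),
                         rng.uniform(miny + pad, maxy - pad))
                   for _ in range(scenario.n_settlements)]
    canals = [_random_chord(rng, grid.bounds) for _ in range(scenario.n_canals)]
    roads = [_random_chord(rng, grid.bounds) for _ in range(scenario.n_roads)]

    # initial land cover
    classes = np.where(peat_depth > np.median(peat_depth),
                       F.LC_CLASSES["swamp_forest"], F.LC_CLASSES["dry_forest"])
    patchiness = gaussian_filter(rng.normal(size=shape), sigma=4)
    classes[patchiness > 1.0] = F.LC_CLASSES["swamp_scrub"]
    classes[patchiness < -1.2] = F.LC_CLASSES["scrub_bare"]
    crops = gaussian_filter(rng.normal(size=shape), sigma=3)
    classes[(crops > 1.3)] = F.LC_CLASSES["riceland"]
    classes[(crops < -1.5)] = F.LC_CLASSES["plantation"]
    classes[elevation < np.percentile(elevation, 2)] = F.LC_CLASSES["water_cloud"]
    for p in settlements:
        r, c = grid.point_to_rowcol(p.x, p.y)
        classes[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = F.LC_CLASSES["settlement"]
    classes = classes.astype(np.uint8)

    forest_codes = [F.LC_CLASSES[c] for c in F.DEFAULT_FOREST_CLASSES]
    land_cover: dict[int, F.LandCoverMap] = {}
    current = classes
    for date in scenario.map_dates:
        if date != scenario.map_dates[0]:
            nxt = current.copy()
            forest = np.isin(current, forest_codes)
            cleared = forest & (rng.uniform(size=shape) < scenario.clearance_rate)
            nxt[cleared] = F.LC_CLASSES["swamp_scrub"]
            current = nxt
        land_cover[date] = F.LandCoverMap(grid=grid, classes=current, map_year=date)

    return LandscapeBundle(grid=grid, land_cover=land_cover, elevation=elevation,
                           peat_depth=peat_depth, settlements=settlements,
                           canals=canals, roads=roads)


# ---------------------------------------------------------------------------
# Monthly series
# ---------------------------------------------------------------------------

_DRY_MONTHS = (5, 6, 7, 8, 9, 10)

_NDVI_BY_CLASS = {
    "dry_forest": 0.85, "swamp_forest": 0.80, "swamp_scrub": 0.45,
    "scrub_bare": 0.30, "riceland": 0.50, "plantation": 0.65,
    "settlement": 0.20, "water_cloud": 0.05,
}


def _precip_climatology(month: int) -> float:
    """Monthly precipitation (mm) with a wet-season (Nov-Apr) peak."""
    return 210.0 + 100.0 * math.cos(2 * math.pi * (month - 1) / 12)


def _pet_climatology(month: int) -> float:
    """Monthly potential evapotranspiration (mm), peaking in the dry season."""
    return 130.0 - 25.0 * math.cos(2 * math.pi * (month - 1) / 12)


def generate_monthly_series(scenario: SyntheticScenario, grid: GridSpec,
                            landscape: LandscapeBundle,
                            burned_by_year: dict[int, np.ndarray] | None = None,
                            ) -> MonthlySeries:
    """Monthly NDVI/EVI/ET/PET on the analysis grid and coarse precipitation.

    Precipitation follows a sinusoidal annual cycle whose dry-season
    (May-October) totals shrink as the year's ONI rises (El Nino drought
    forcing), with multiplicative gamma noise of coefficient of variation
    ``precip_noise_cv`` per coarse pixel and month — monthly tropical
    rainfall is strongly right-skewed, which is also what keeps the
    drought-index distribution fit well-posed. With all-zero ONI and
    ``precip_noise_cv=0`` the climatology repeats identically every year.
    Vegetation indices are set by land-cover class, depressed where
    ``burned_by_year`` records fire in a preceding year, and a
    ``missing_fraction`` of pixels per month is masked to exercise gap
    filling. Weather (precip/PET) spans ``scenario.weather_years``;
    vegetation layers only the study years.
    """
    rng = _rng(scenario.seed, "series")
    shape = grid.shape
    precip_grid = grid.coarsen(10)
    burned_by_year = burned_by_year or {}

    # static spatial patterns (shared across years so ONI is the only
    # inter-annual forcing unless precip_interannual_cv > 0)
    precip_pattern = 1.0 + 0.1 * np.linspace(-1, 1, precip_grid.n_cols)[None, :] \
        + 0.05 * gaussian_filter(rng.normal(size=precip_grid.shape), sigma=2)
    veg_pattern = 0.05 * gaussian_filter(rng.normal(size=shape), sigma=3)

    precip: dict[tuple[int, int], np.ndarray] = {}
    pet: dict[tuple[int, int], np.ndarray] = {}
    cv = scenario.precip_noise_cv
    for year in scenario.weather_years:
        oni = scenario.oni_for(year)
        for month in range(1, 13):
            base = _precip_climatology(month)
            if month in _DRY_MONTHS:
                base *= max(0.05, 1.0 - 0.35 * oni)
            if cv > 0:
                noise = rng.gamma(1 / cv ** 2, cv ** 2, size=precip_grid.shape)
            else:
                noise = 1.0
            precip[(year, month)] = np.maximum(base * noise * precip_pattern, 1.0)
            pet[(year, month)] = np.full(shape, _pet_climatology(month))

    ndvi: dict[tuple[int, int], np.ndarray] = {}
    evi: dict[tuple[int, int], np.ndarray] = {}
    et: dict[tuple[int, int], np.ndarray] = {}
    for year in scenario.years:
        lc = landscape.landcover_for_year(year)
        base = np.zeros(shape)
        for name, code in F.LC_CLASSES.items():
            base[lc.classes == code] = _NDVI_BY_CLASS[name]
        burn_factor = np.ones(shape)
        for by, mask in burned_by_year.items():
            lag = year - by
            if lag == 1:
                burn_factor[mask] = np.minimum(burn_factor[mask], 0.5)
            elif lag == 2:
                burn_factor[mask] = np.minimum(burn_factor[mask], 0.75)
        oni = scenario.oni_for(year)
        for month in range(1, 13):
            dry_stress = 0.10 * (1 + 0.3 * oni) if month in (8, 9, 10) else 0.0
            nd = np.clip(base * burn_factor * (1 - dry_stress) + veg_pattern, 0.0, 1.0)
            ev = np.clip(0.65 * nd + 0.02, 0.0, 1.0)
            moisture = np.clip(0.35 + 0.6 * nd - dry_stress, 0.05, 0.95)
            e = pet[(year, month)] * moisture
            if scenario.missing_fraction > 0:
                missing = rng.uniform(size=shape) < scenario.missing_fraction
                nd, ev, e = (np.where(missing, np.nan, a) for a in (nd, ev, e))
            ndvi[(year, month)], evi[(year, month)], et[(year, month)] = nd, ev, e

    return MonthlySeries(grid=grid, precip_grid=precip_grid, precip=precip,
                         ndvi=ndvi, evi=evi, et=et, pet=pet)


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

def _minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        return np.full(arr.shape, 0.5)
    return (arr - lo) / (hi - lo)


def fire_probability(scenario: SyntheticScenario, grid: GridSpec,
                     landscape: LandscapeBundle, series: MonthlySeries,
                     year: int) -> np.ndarray:
    """The planted per-cell, per-month burn probability for one year."""
    w = scenario.driver_weights
    drivers: dict[str, np.ndarray] = {}
    if "dist_settlements" in w:
        drivers["dist_settlements"] = _minmax(
            F.distance_raster(landscape.settlements, grid))
    if "dist_canals" in w:
        drivers["dist_canals"] = _minmax(F.distance_raster(landscape.canals, grid))
    if "dist_roads" in w:
        drivers["dist_roads"] = _minmax(F.distance_raster(landscape.roads, grid))
    if "oni" in w:
        onis = [scenario.oni_for(y) for y in scenario.years]
        lo, hi = min(onis), max(onis)
        z = 0.5 if hi == lo else (scenario.oni_for(year) - lo) / (hi - lo)
        drivers["oni"] = np.full(grid.shape, z)
    if "ndvi" in w:
        pre = np.nanmean([series.ndvi[(year, m)] for m in F.PRE_FIRE_MONTHS], axis=0)
        pre = np.where(np.isfinite(pre), pre, np.nanmean(pre))
        drivers["ndvi"] = _minmax(pre)

    logodds = np.full(grid.shape, logit(scenario.base_rate))
    for name, weight in w.items():
        if name not in drivers:
            raise KeyError(f"no driver available for weight {name!r}")
        logodds = logodds + weight * (drivers[name] - 0.5)
    return expit(logodds)


def generate_hotspots(scenario: SyntheticScenario, grid: GridSpec,
                      landscape: LandscapeBundle, series: MonthlySeries,
                      ) -> tuple[dict[int, list[HotspotRecord]], dict[int, np.ndarray]]:
    """Seeded fire draws and satellite-style detections for every study year.

    Returns (hotspots_by_year, burned_mask_by_year); the burned masks are
    the ground truth that downstream oracle tests compare against.
    """
    rng = _rng(scenario.seed, "hotspots")
    hotspots: dict[int, list[HotspotRecord]] = {}
    burned: dict[int, np.ndarray] = {}
    xm, ym = grid.center_mesh()
    for year in scenario.years:
        p = fire_probability(scenario, grid, landscape, series, year)
        year_mask = np.zeros(grid.shape, dtype=bool)
        records: list[HotspotRecord] = []
        for month in F.FIRE_MONTHS:
            burn = rng.uniform(size=grid.shape) < p
            year_mask |= burn
            rows, cols = np.nonzero(burn)
            for r, c in zip(rows, cols):
                # one fire: a fixed true location inside the burning cell,
                # observed by one sensor across 1 + Poisson repeat passes
                k = 1 + rng.poisson(max(scenario.emission_mean - 1.0, 0.0))
                if year >= VIIRS_FIRST_YEAR and rng.uniform() < 0.5:
                    sensor = "VIIRS"
                else:
                    sensor = "MODIS"
                res = SENSOR_RESOLUTION[sensor]
                jx = xm[r, c] + rng.uniform(-0.5, 0.5) * grid.cell_size
                jy = ym[r, c] + rng.uniform(-0.5, 0.5) * grid.cell_size
                sx, sy = grid.snap_to_centers(jx, jy, cell_size=res)
                for _ in range(k):
                    if rng.uniform() < scenario.detection_drop_rate:
                        continue
                    day = int(rng.integers(1, 29))
                    records.append(HotspotRecord(
                        x=float(sx), y=float(sy),
                        date=_dt.date(year, month, day),
                        sensor=sensor, nominal_resolution=res))
        hotspots[year] = records
        burned[year] = year_mask
    return hotspots, burned


def generate_cloud_masks(scenario: SyntheticScenario, grid: GridSpec, year: int,
                         p_cloud: float = 0.45,
                         season_days: int = 123) -> np.ndarray:
    """Daily boolean cloud masks for the July-October fire season.

    A simple stand-in for satellite cloud-state flags: per-pixel Bernoulli
    draws around a smooth daily cloudiness level.
    """
    rng = np.random.default_rng([scenario.seed, _STAGE["clouds"], year])
    daily_level = np.clip(
        p_cloud + 0.15 * np.sin(np.linspace(0, 6 * np.pi, season_days)), 0, 1)
    return rng.uniform(size=(season_days,) + grid.shape) < daily_level[:, None, None]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    scenario: SyntheticScenario
    grid: GridSpec
    landscape: LandscapeBundle
    series: MonthlySeries
    hotspots: dict[int, list[HotspotRecord]]
    burned: dict[int, np.ndarray]


def simulate_scenario(scenario: SyntheticScenario, grid: GridSpec) -> ScenarioResult:
    """Run the full generator: landscape, weather, fires, then a second
    vegetation pass in which cells burned in earlier years show depressed
    indices (fire scars feed back into the vegetation record, as on real
    imagery, without altering the fire draws themselves)."""
    landscape = generate_landscape(scenario, grid)
    series0 = generate_monthly_series(scenario, grid, landscape)
    hotspots, burned = generate_hotspots(scenario, grid, landscape, series0)
    series = generate_monthly_series(scenario, grid, landscape, burned_by_year=burned)
    return ScenarioResult(scenario=scenario, grid=grid, landscape=landscape,
                          series=series, hotspots=hotspots, burned=burned)
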