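"""End-to-end assembly: scenario outputs -> per-year feature stacks -> models.

This is the glue a study run uses: it gap-fills the vegetation record,
builds ET:PET ratios and seasonal aggregates, downscales precipitation and
computes the 3- and 12-month drought indices, derives distances, terrain,
land-cover expansion and the clearance index, then min-max normalizes
everything with min/max pooled across the training years.
"""

from __future__ import annotations

import numpy as np

from . import features as F
from . import hotspots as H
from . import spei as S
from .synthetic import ScenarioResult


def _seasonal_triplet(monthly: dict[int, np.ndarray], prefix: str,
                      layers: dict[str, np.ndarray]) -> None:
    pre = F.seasonal_aggregate(monthly, F.PRE_FIRE_MONTHS)
    layers[f"{prefix}_pre"] = pre
    layers[f"{prefix}_fire"] = F.seasonal_aggregate(monthly, F.FIRE_MONTHS)
    layers[f"{prefix}_delta"] = F.delta_aug_prefs(monthly, pre)


def build_feature_stacks(result: ScenarioResult, normalize: bool = True,
                         ) -> tuple[dict[int, F.SeasonalFeatureStack],
                                    dict[str, F.NormalizationParams]]:
    """Per-year predictor stacks for all study years of a scenario.

    Drought-index layers are the August SPEI (start of the fire season)
    at 3- and 12-month scales, fitted over the full weather record; pixels
    with an undefined distribution fit are infilled from their 5x5
    neighbourhood like any other missing raster value.
    """
    sc, grid, land, series = (result.scenario, result.grid,
                              result.landscape, result.series)

    fine_precip = {ym: F.interpolate_precip(v, series.precip_grid, grid)
                   for ym, v in series.precip.items()}
    spei3, _ = S.spei_series(fine_precip, series.pet, scale_months=3)
    spei12, _ = S.spei_series(fine_precip, series.pet, scale_months=12)

    dist = {
        "dist_settlements": F.distance_raster(land.settlements, grid),
        "dist_canals": F.distance_raster(land.canals, grid),
        "dist_roads": F.distance_raster(land.roads, grid),
    }
    slope, aspect = F.terrain_derivatives(land.elevation, grid)
    aspect = np.where(np.isfinite(aspect), aspect, 0.0)  # flat cells -> north

    raw_stacks: dict[int, dict[str, np.ndarray]] = {}
    for year in sc.years:
        layers: dict[str, np.ndarray] = {}
        months = range(1, 13)
        et = {m: F.gap_fill(series.et[(year, m)]) for m in months}
        pet = {m: series.pet[(year, m)] for m in months}
        etpet = {m: F.et_pet_ratio(et[m], pet[m]) for m in months}
        ndvi = {m: F.gap_fill(series.ndvi[(year, m)]) for m in months}
        evi = {m: F.gap_fill(series.evi[(year, m)]) for m in months}
        _seasonal_triplet(etpet, "etpet", layers)
        _seasonal_triplet(ndvi, "ndvi", layers)
        _seasonal_triplet(evi, "evi", layers)

        layers["spei3"] = F.gap_fill(spei3[(year, 8)])
        layers["spei12"] = F.gap_fill(spei12[(year, 8)])
        layers.update(dist)
        layers.update(F.binary_expand(land.landcover_for_year(year)))
        maps = [land.land_cover[d] for d in sorted(land.land_cover) if d <= year]
        layers["clearance_index"] = F.forest_clearance_index(
            maps, target_map_year=year).values.astype(float)
        layers["oni"] = F.oni_layer({year: sc.oni_for(year)}, year, grid)
        layers["elevation"] = land.elevation
        layers["slope"] = slope
        layers["aspect"] = aspect
        layers["peat_depth"] = land.peat_depth
        raw_stacks[year] = layers

    if normalize:
        normalized, params = F.cross_year_normalize(raw_stacks,
                                                    on_constant="passthrough")
    else:
        normalized, params = raw_stacks, {}
    stacks = {year: F.SeasonalFeatureStack(grid=grid, year=year, layers=layers)
              for year, layers in normalized.items()}
    return stacks, params


def sample_points_all_years(result: ScenarioResult, n_pos: int, n_neg: int,
                            seed: int) -> list[H.TrainingPoint]:
    """QC, partition, and sample positives/negatives for every study year."""
    points: list[H.TrainingPoint] = []
    bounds = result.grid.bounds_polygon
    for year in result.scenario.years:
        labelled = H.classify_confidence(result.hotspots[year], result.grid)
        spaces = H.build_occurrence_spaces(labelled, bounds)
        points.extend(H.sample_training_points(
            spaces, n_pos=n_pos, n_neg=n_neg, year=year,
            seed=np.random.default_rng([seed, year]).integers(2 ** 31)))
    return points


def density_maps(result: ScenarioResult) -> dict[int, H.DensityMap]:
    return {year: H.density_map(result.hotspots[year], result.grid, year)
            for year in result.scenario.years}
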