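"""Hotspot quality control, occurrence spaces, sampling, and density maps.

Satellite fire detections are noisy: a single isolated detection may be a
false positive, while repeated detections in the same place within a short
window are almost certainly real fire. The processing chain here encodes
that: points are split into high/low confidence on a 500 m QC grid with a
30-day companion window, buffered and dissolved into a three-way partition
of the study area, and training points are drawn from the two
high-confidence spaces. Density maps use *all* detections, without QC,
and serve as the observation side of validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .exceptions import GeometryError, SamplingError
from .grids import GridSpec
from .records import HotspotRecord

BUFFER_QUAD_SEGS = 16  # segments per quarter circle in buffer polygons


@dataclass(frozen=True)
class ConfidenceLabelledHotspot:
    record: HotspotRecord
    confidence: str  # "high" | "low"
    qc_cell_id: int


@dataclass
class OccurrenceSpaces:
    """Disjoint partition of the study area by fire-detection confidence."""

    high_fire_space: BaseGeometry
    low_fire_space: BaseGeometry
    non_occurrence_space: BaseGeometry
    study_bounds: BaseGeometry


@dataclass(frozen=True)
class TrainingPoint:
    x: float
    y: float
    year: int
    label: int  # 1 fire, 0 non-fire


@dataclass
class DensityMap:
    grid: GridSpec
    values: np.ndarray  # hotspots per km^2 per cell
    year: int


def classify_confidence(hotspots: list[HotspotRecord], grid: GridSpec,
                        qc_cell_size: float = 500.0, window_days: int = 30,
                        ) -> list[ConfidenceLabelledHotspot]:
    """Split hotspots into high/low confidence on a QC grid.

    A hotspot is high-confidence iff at least one other hotspot falls in
    the same QC cell within ``window_days`` (inclusive) of it; cells with
    a single hotspot, or where every companion is further apart in time,
    are low-confidence. The QC grid is anchored at the grid origin with
    half-open cells, so assignment is deterministic; labels do not depend
    on input order.
    """
    if not hotspots:
        return []
    xs = np.array([h.x for h in hotspots])
    ys = np.array([h.y for h in hotspots])
    days = np.array([h.date.toordinal() for h in hotspots])
    col = np.floor((xs - grid.origin_x) / qc_cell_size).astype(np.int64)
    row = np.floor((grid.origin_y - ys) / qc_cell_size).astype(np.int64)
    cell_id = row * np.int64(2 ** 31) + col  # collision-free row/col pairing

    high = np.zeros(len(hotspots), dtype=bool)
    order = np.lexsort((days, cell_id))
    sc, sd = cell_id[order], days[order]
    same_cell = sc[1:] == sc[:-1]
    close = np.abs(sd[1:] - sd[:-1]) <= window_days
    pair = same_cell & close
    # within a cell sorted by date, the nearest-in-time companion is adjacent
    is_high_sorted = np.zeros(len(hotspots), dtype=bool)
    is_high_sorted[:-1] |= pair
    is_high_sorted[1:] |= pair
    high[order] = is_high_sorted

    return [ConfidenceLabelledHotspot(record=h,
                                      confidence="high" if hi else "low",
                                      qc_cell_id=int(c))
            for h, hi, c in zip(hotspots, high, cell_id)]


def build_occurrence_spaces(labelled: list[ConfidenceLabelledHotspot],
                            study_bounds: BaseGeometry,
                            buffer_m: float = 500.0,
                            quad_segs: int = BUFFER_QUAD_SEGS) -> OccurrenceSpaces:
    """Buffer-dissolve the labelled points into three disjoint spaces.

    High-confidence space is the dissolved buffers around high points; the
    low space is the dissolved low buffers minus the high space; the rest
    of the study bounds is the non-occurrence space. Low buffers are
    subtracted from the high space (not vice versa) so the partition is
    exact and the positive training space keeps priority.
    """
    if study_bounds.area <= 0:
        raise GeometryError("study bounds have zero area")

    def dissolved(points):
        if not points:
            return shapely.Polygon()
        geoms = [shapely.Point(p.record.x, p.record.y).buffer(buffer_m,
                                                              quad_segs=quad_segs)
                 for p in points]
        return shapely.union_all(geoms)

    high_pts = [p for p in labelled if p.confidence == "high"]
    low_pts = [p for p in labelled if p.confidence == "low"]
    high = dissolved(high_pts).intersection(study_bounds)
    low = dissolved(low_pts).intersection(study_bounds).difference(high)
    non = study_bounds.difference(high).difference(low)
    return OccurrenceSpaces(high_fire_space=high, low_fire_space=low,
                            non_occurrence_space=non, study_bounds=study_bounds)


def sample_training_points(spaces: OccurrenceSpaces, n_pos: int, n_neg: int,
                           year: int, seed: int) -> list[TrainingPoint]:
    """Uniform random points: n_pos from the high-fire space (label 1) and
    n_neg from the non-occurrence space (label 0), by rejection sampling."""
    if n_pos <= 0 or n_neg <= 0:
        raise SamplingError("requested point counts must be positive")
    rng = np.random.default_rng(seed)
    out: list[TrainingPoint] = []
    for space, n, label, name in (
            (spaces.high_fire_space, n_pos, 1, "high-fire"),
            (spaces.non_occurrence_space, n_neg, 0, "non-occurrence")):
        if space.is_empty or space.area <= 0:
            raise SamplingError(
                f"{name} space is empty for year {year}; cannot draw {n} points")
        minx, miny, maxx, maxy = space.bounds
        got = 0
        attempts = 0
        while got < n:
            attempts += 1
            if attempts > 10000:
                raise SamplingError(
                    f"rejection sampling stalled in {name} space for year {year}")
            batch = max(64, 2 * (n - got))
            xs = rng.uniform(minx, maxx, batch)
            ys = rng.uniform(miny, maxy, batch)
            inside = shapely.contains_xy(space, xs, ys)
            for x, y in zip(xs[inside], ys[inside]):
                if got == n:
                    break
                out.append(TrainingPoint(x=float(x), y=float(y), year=year,
                                         label=label))
                got += 1
    return out


def density_map(hotspots: list[HotspotRecord], grid: GridSpec,
                year: int) -> DensityMap:
    """Per-cell hotspot density (detections per km^2) for one year.

    Uses all hotspots of the year inside the grid, without any confidence
    filtering, so the map is an independent observation of fire activity.
    """
    values = np.zeros(grid.shape)
    sel = [h for h in hotspots if h.date.year == year]
    if sel:
        xs = np.array([h.x for h in sel])
        ys = np.array([h.y for h in sel])
        keep = grid.contains_points(xs, ys)
        row, col = grid.point_to_rowcol(xs[keep], ys[keep])
        np.add.at(values, (row, col), 1.0)
    values /= grid.cell_area_km2
    return DensityMap(grid=grid, values=values, year=year)


def count_cloud_days(daily_cloud_masks: np.ndarray, grid: GridSpec,
                     study_bounds: BaseGeometry | None = None) -> float:
    """Mean number of cloudy days per pixel over the fire season.

    ``daily_cloud_masks`` is a (n_days, n_rows, n_cols) boolean stack; the
    per-pixel count of cloudy days is averaged (unweighted) over pixels
    inside the study bounds (all pixels when no bounds are given).
    """
    masks = np.asarray(daily_cloud_masks)
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise ValueError("need a non-empty (days, rows, cols) mask stack")
    per_pixel = masks.sum(axis=0).astype(float)
    if study_bounds is not None:
        xm, ym = grid.center_mesh()
        inside = shapely.contains_xy(study_bounds, xm.ravel(), ym.ravel())
        inside = inside.reshape(grid.shape)
        if not inside.any():
            raise GeometryError("study bounds contain no pixel centres")
        per_pixel = per_pixel[inside]
    return float(per_pixel.mean())
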