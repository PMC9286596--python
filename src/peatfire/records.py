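"""Fire-detection point records and their CSV interchange format.

A hotspot is a satellite thermal-anomaly detection reported at the centre
of a sensor grid cell (1 km for MODIS, 375 m for VIIRS), not an exact fire
location. The CSV schema (x, y, date, sensor, nominal_resolution) is the
common core of the MODIS/VIIRS active-fire exports this package consumes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

SENSORS = ("MODIS", "VIIRS")
SENSOR_RESOLUTION = {"MODIS": 1000, "VIIRS": 375}
VIIRS_FIRST_YEAR = 2012


@dataclass(frozen=True)
class HotspotRecord:
    x: float
    y: float
    date: _dt.date
    sensor: str
    nominal_resolution: int

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}")
        if self.nominal_resolution not in (1000, 375):
            raise ValueError("nominal_resolution must be 1000 or 375 m")


def hotspots_to_frame(hotspots: list[HotspotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [h.x for h in hotspots],
            "y": [h.y for h in hotspots],
            "date": [h.date.isoformat() for h in hotspots],
            "sensor": [h.sensor for h in hotspots],
            "nominal_resolution": [h.nominal_resolution for h in hotspots],
        }
    )


def frame_to_hotspots(df: pd.DataFrame) -> list[HotspotRecord]:
    return [
        HotspotRecord(
            x=float(r.x),
            y=float(r.y),
            date=_dt.date.fromisoformat(str(r.date)[:10]),
            sensor=str(r.sensor),
            nominal_resolution=int(r.nominal_resolution),
        )
        for r in df.itertuples()
    ]


def write_hotspot_csv(path: str | Path, hotspots: list[HotspotRecord]) -> None:
    hotspots_to_frame(hotspots).to_csv(path, index=False)


def read_hotspot_csv(path: str | Path) -> list[HotspotRecord]:
    return frame_to_hotspots(pd.read_csv(path))
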