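"""Minimal georeferenced raster container and GeoTIFF/GeoJSON I/O.

Rasters are north-up regular grids in a single projected CRS (metres);
``origin_x``/``origin_y`` are the coordinates of the *top-left corner* of
the top-left pixel. Georeferencing and provenance travel in the TIFF
ImageDescription tag as JSON, which keeps the files plain single-band
GeoTIFF-shaped TIFFs readable by any TIFF reader.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

DEFAULT_CRS = "EPSG:32647"  # WGS 84 / UTM zone 47N


@dataclass
class Raster:
    data: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    crs: str = DEFAULT_CRS
    timestamp: datetime.date | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        ny, nx = self.data.shape
        return (
            self.origin_x,
            self.origin_y - ny * self.pixel_size,
            self.origin_x + nx * self.pixel_size,
            self.origin_y,
        )

    def pixel_polygon(self, row: int, col: int) -> BaseGeometry:
        """Exact footprint of pixel (row, col) as a shapely box."""
        x0 = self.origin_x + col * self.pixel_size
        y1 = self.origin_y - row * self.pixel_size
        return box(x0, y1 - self.pixel_size, x0 + self.pixel_size, y1)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_centers, y_centers) along columns and rows."""
        ny, nx = self.data.shape
        xs = self.origin_x + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(ny) + 0.5) * self.pixel_size
        return xs, ys

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.pixel_size == other.pixel_size
            and self.crs == other.crs
        )

    # -- I/O -----------------------------------------------------------

    def write(self, path: str | Path) -> None:
        desc = {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "crs": self.crs,
            "timestamp": self.timestamp.isoformat() if self.timestamp else None,
            "meta": self.meta,
        }
        tifffile.imwrite(
            Path(path),
            self.data.astype(np.float32),
            description=json.dumps(desc, sort_keys=True),
        )

    @classmethod
    def read(cls, path: str | Path) -> "Raster":
        with tifffile.TiffFile(Path(path)) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(float)
            desc = json.loads(page.description)
        ts = desc.get("timestamp")
        return cls(
            data=data,
            origin_x=desc["origin_x"],
            origin_y=desc["origin_y"],
            pixel_size=desc["pixel_size"],
            crs=desc.get("crs", DEFAULT_CRS),
            timestamp=datetime.date.fromisoformat(ts) if ts else None,
            meta=desc.get("meta", {}),
        )


def write_geojson(geometries: list[tuple[BaseGeometry, dict]], path: str | Path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in geometries
        ],
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]
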