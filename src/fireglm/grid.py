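"""Grid geometry for 0.5-degree global (or regional) raster analysis.

Cell areas follow the spherical-zone formula
``A = R^2 * dlon * (sin(lat + dlat/2) - sin(lat - dlat/2))`` so that a full
global grid integrates to the Earth's surface area (~5.10e8 km^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridDefinition:
    """Regular lat/lon grid with per-cell areas in km^2.

    Parameters
    ----------
    lon_centers, lat_centers : 1-d arrays of cell-center coordinates
        (degrees east / degrees north).
    resolution : cell edge length in degrees (default 0.5).
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    resolution: float = 0.5
    cell_area: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lon = np.asarray(self.lon_centers, dtype=float)
        lat = np.asarray(self.lat_centers, dtype=float)
        if lon.ndim != 1 or lon.size == 0:
            raise ValueError("invalid grid: lon_centers must be a non-empty 1-d array")
        if lat.ndim != 1 or lat.size == 0:
            raise ValueError("invalid grid: lat_centers must be a non-empty 1-d array")
        if self.resolution <= 0:
            raise ValueError("invalid grid: resolution must be positive")
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("invalid grid: lat_centers outside [-90, 90]")
        object.__setattr__(self, "lon_centers", lon)
        object.__setattr__(self, "lat_centers", lat)
        if self.cell_area is None:
            object.__setattr__(self, "cell_area", self._compute_areas())

    def _compute_areas(self) -> np.ndarray:
        half = self.resolution / 2.0
        lat = self.lat_centers
        band = (
            EARTH_RADIUS_KM**2
            * np.deg2rad(self.resolution)
            * (np.sin(np.deg2rad(np.clip(lat + half, -90, 90)))
               - np.sin(np.deg2rad(np.clip(lat - half, -90, 90))))
        )
        # broadcast to (nlat, nlon); zonally constant
        return np.repeat(band[:, None], self.lon_centers.size, axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def n_cells(self) -> int:
        return self.lat_centers.size * self.lon_centers.size

    def lat_field(self) -> np.ndarray:
        """Per-cell latitude, shape ``self.shape``."""
        return np.repeat(self.lat_centers[:, None], self.lon_centers.size, axis=1)


def global_grid(resolution: float = 0.5) -> GridDefinition:
    """Full global grid at the given resolution."""
    half = resolution / 2.0
    lon = np.arange(-180 + half, 180, resolution)
    lat = np.arange(-90 + half, 90, resolution)
    return GridDefinition(lon_centers=lon, lat_centers=lat, resolution=resolution)


def demo_grid(nlon: int = 40, nlat: int = 20, resolution: float = 0.5,
              lat0: float = 40.0, lon0: float = 0.0) -> GridDefinition:
    """Desk-scale regional grid (default 40 x 20 cells spanning 40-50N)."""
    half = resolution / 2.0
    lon = lon0 + half + resolution * np.arange(nlon)
    lat = lat0 + half + resolution * np.arange(nlat)
    return GridDefinition(lon_centers=lon, lat_centers=lat, resolution=resolution)
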