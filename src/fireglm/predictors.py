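"""The 16-predictor layout and gridded field containers.

Predictor names and order follow the standard covariate set used in
empirical fire-regime GLMs: climate (DD, DD_s, VPD, DTR, wind), vegetation
(GPP, GPP_s, grass, shrub, tree), human activity (popd, crop, roads),
topography (VRM, TPI) and ignitions (light).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridDefinition

#: canonical predictor order; attribution tie-breaks use this index order
PREDICTORS: tuple[str, ...] = (
    "DD",      # mean monthly number of dry days
    "DD_s",    # dry-day seasonality, range/mean
    "VPD",     # maximum monthly vapour pressure deficit, kPa
    "DTR",     # diurnal temperature range of the month with largest DTR, degC
    "wind",    # wind speed of the hottest month, m s-1
    "GPP",     # annual gross primary production, training units
    "GPP_s",   # GPP seasonality, range/mean
    "grass",   # fractional grass cover
    "shrub",   # fractional shrub cover
    "tree",    # fractional tree cover
    "popd",    # population density, persons km-2
    "crop",    # fractional cropland cover
    "roads",   # road density, km km-2
    "VRM",     # vector ruggedness metric
    "TPI",     # topographic position index
    "light",   # mean monthly lightning ground strikes
)

#: factor-group membership for the sensitivity experiments
CLIMATE_PREDICTORS: tuple[str, ...] = ("DD", "DD_s", "VPD", "DTR", "wind")
VEGETATION_PREDICTORS: tuple[str, ...] = ("GPP", "GPP_s", "grass", "shrub", "tree")
HUMAN_PREDICTORS: tuple[str, ...] = ("popd", "crop", "roads")
CONSTANT_PREDICTORS: tuple[str, ...] = ("VRM", "TPI", "light")

FRACTIONAL_PREDICTORS: tuple[str, ...] = ("grass", "shrub", "tree", "crop")
NONNEGATIVE_PREDICTORS: tuple[str, ...] = (
    "DD", "VPD", "wind", "GPP", "GPP_s", "DD_s", "popd", "roads", "light", "VRM",
)


class LayoutError(ValueError):
    """Predictor layout does not match the canonical 16-name set."""


def check_layout(names) -> None:
    missing = [p for p in PREDICTORS if p not in names]
    extra = [n for n in names if n not in PREDICTORS]
    if missing or extra:
        raise LayoutError(
            f"predictor layout mismatch: missing={missing}, unexpected={extra}"
        )


@dataclass
class PredictorField:
    """All 16 predictor layers on one grid.

    ``data`` maps predictor name -> 2-d array of shape ``grid.shape``.
    """

    grid: GridDefinition
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_layout(self.data.keys())
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {self.grid.shape}"
                )
            self.data[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        if name not in PREDICTORS:
            raise LayoutError(f"unknown predictor {name!r}")
        value = np.asarray(value, dtype=float)
        if value.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} has wrong shape {value.shape}")
        self.data[name] = value

    def copy(self) -> "PredictorField":
        return PredictorField(self.grid, {k: v.copy() for k, v in self.data.items()})

    def matrix(self) -> np.ndarray:
        """Design matrix of shape (n_cells, 16), columns in canonical order."""
        return np.column_stack([self.data[p].ravel() for p in PREDICTORS])

    def validate_ranges(self) -> None:
        """Raise if any layer violates its physical range."""
        for name in PREDICTORS:
            arr = self.data[name]
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} contains non-finite values")
            if name in FRACTIONAL_PREDICTORS and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"fractional layer {name!r} outside [0, 1]")
            if name in NONNEGATIVE_PREDICTORS and arr.min() < 0:
                raise ValueError(f"layer {name!r} has negative values")
        covers = self.data["tree"] + self.data["grass"] + self.data["shrub"]
        if covers.max() > 1 + 1e-9:
            raise ValueError("tree + grass + shrub exceeds 1 in some cell")

    # ------------------------------------------------------------------ I/O
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {name: (("lat", "lon"), self.data[name]) for name in PREDICTORS},
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
            attrs={"resolution": self.grid.resolution},
        )
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "PredictorField":
        grid = GridDefinition(
            lon_centers=np.asarray(ds["lon"].values),
            lat_centers=np.asarray(ds["lat"].values),
            resolution=float(ds.attrs.get("resolution", 0.5)),
        )
        data = {name: np.asarray(ds[name].values, dtype=float) for name in PREDICTORS}
        return cls(grid, data)

    @classmethod
    def from_netcdf(cls, path) -> "PredictorField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (cell_id, predictor, value)."""
        n = self.grid.n_cells
        frames = [
            pd.DataFrame(
                {"cell_id": np.arange(n), "predictor": name,
                 "value": self.data[name].ravel()}
            )
            for name in PREDICTORS
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class FireObservations:
    """Per-cell fire properties: burnt-area fraction, median fire size (km^2)
    and median fire intensity (FRP / sqrt(fire size), W km-1)."""

    grid: GridDefinition
    BA: np.ndarray
    FS: np.ndarray
    FI: np.ndarray

    def __post_init__(self) -> None:
        for name in ("BA", "FS", "FI"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {self.grid.shape}")
            setattr(self, name, arr)

    def validate(self) -> None:
        if self.BA.min() < 0 or self.BA.max() > 1:
            raise ValueError("BA outside [0, 1]")
        if self.FS.min() < 0 or self.FI.min() < 0:
            raise ValueError("FS/FI negative")
        zero = self.BA == 0
        if np.any(self.FS[zero] != 0) or np.any(self.FI[zero] != 0):
            raise ValueError("FS/FI nonzero on zero-BA cells")

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"BA": (("lat", "lon"), self.BA),
             "FS": (("lat", "lon"), self.FS),
             "FI": (("lat", "lon"), self.FI)},
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
            attrs={"resolution": self.grid.resolution},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "FireObservations":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        grid = GridDefinition(
            lon_centers=np.asarray(ds["lon"].values),
            lat_centers=np.asarray(ds["lat"].values),
            resolution=float(ds.attrs.get("resolution", 0.5)),
        )
        return cls(grid, np.asarray(ds["BA"].values), np.asarray(ds["FS"].values),
                   np.asarray(ds["FI"].values))
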