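"""Gridded environment container: daily ice concentration plus static bathymetry.

Grids are regular in longitude/latitude, indexed ``[lat, lon]`` with both
coordinate axes ascending and coordinates at cell centres. Sampling is
nearest-cell (no interpolation): a point maps to the cell whose edges contain
it, by floor index arithmetic on the cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Sequence

import numpy as np

from .errors import MissingLayerError, OutOfExtentError

__all__ = ["EnvStack"]


def _as_date(d) -> date:
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, date):
        return d
    if isinstance(d, np.datetime64):
        return d.astype("datetime64[D]").astype(object)
    return date.fromisoformat(str(d)[:10])


@dataclass
class EnvStack:
    """Daily ice grids, a bathymetry grid, and a land mask on a shared grid.

    Attributes
    ----------
    lon, lat
        1-D ascending cell-centre coordinates in degrees.
    dates
        Calendar dates of the ice layers, one per leading ``ice`` index.
    ice
        ``(n_days, nlat, nlon)`` percent concentration in [0, 100]; NaN on land.
    depth
        ``(nlat, nlon)`` seafloor depth in metres, positive down; NaN on land.
    land
        ``(nlat, nlon)`` boolean, True where the cell is land.
    """

    lon: np.ndarray
    lat: np.ndarray
    dates: list
    ice: np.ndarray
    depth: np.ndarray
    land: np.ndarray
    _date_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.dates = [_as_date(d) for d in self.dates]
        self.ice = np.asarray(self.ice, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.land = np.asarray(self.land, dtype=bool)
        if self.lon.size < 2 or self.lat.size < 2:
            raise OutOfExtentError("grid must have at least 2 cells per axis")
        self._date_index = {d: i for i, d in enumerate(self.dates)}

    # -- grid geometry -------------------------------------------------

    @property
    def cell_deg(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def lon_edges(self) -> np.ndarray:
        d = self.cell_deg
        return np.concatenate((self.lon - d / 2, [self.lon[-1] + d / 2]))

    @property
    def lat_edges(self) -> np.ndarray:
        d = float(self.lat[1] - self.lat[0])
        return np.concatenate((self.lat - d / 2, [self.lat[-1] + d / 2]))

    def in_extent(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        le, la = self.lon_edges, self.lat_edges
        return (lon >= le[0]) & (lon < le[-1]) & (lat >= la[0]) & (lat < la[-1])

    def cell_index(self, lon, lat):
        """(row, col) of the containing cell; raises if out of extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ok = self.in_extent(lon, lat)
        if not np.all(ok):
            bad = np.argwhere(~np.atleast_1d(ok))
            lonb = np.atleast_1d(lon)[bad.ravel()[0]]
            latb = np.atleast_1d(lat)[bad.ravel()[0]]
            raise OutOfExtentError(f"point (lon={lonb}, lat={latb}) outside grid extent")
        col = np.floor((lon - self.lon_edges[0]) / self.cell_deg).astype(int)
        row = np.floor((lat - self.lat_edges[0]) / float(self.lat[1] - self.lat[0])).astype(int)
        col = np.clip(col, 0, self.lon.size - 1)
        row = np.clip(row, 0, self.lat.size - 1)
        return row, col

    def date_layer(self, d) -> int:
        d = _as_date(d)
        try:
            return self._date_index[d]
        except KeyError:
            raise MissingLayerError(f"no ice layer for date {d.isoformat()}") from None

    # -- sampling ------------------------------------------------------

    def is_land(self, lon, lat):
        row, col = self.cell_index(lon, lat)
        return self.land[row, col]

    def sample_ice(self, lon, lat, when):
        """Nearest-cell ice concentration (%) for the layer dated ``when``."""
        k = self.date_layer(when)
        row, col = self.cell_index(lon, lat)
        return self.ice[k][row, col]

    def sample_depth(self, lon, lat):
        """Nearest-cell seafloor depth (m, positive down)."""
        row, col = self.cell_index(lon, lat)
        return self.depth[row, col]

    # -- IO ------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {
                "ice": (("time", "lat", "lon"), self.ice),
                "depth": (("lat", "lon"), self.depth),
                "land": (("lat", "lon"), self.land.astype(np.int8)),
            },
            coords={
                "time": [np.datetime64(d) for d in self.dates],
                "lat": self.lat,
                "lon": self.lon,
            },
        )
        ds.to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        import xarray as xr

        with xr.open_dataset(path) as ds:
            return cls(
                lon=ds["lon"].values,
                lat=ds["lat"].values,
                dates=[_as_date(t) for t in ds["time"].values],
                ice=ds["ice"].values,
                depth=ds["depth"].values,
                land=ds["land"].values.astype(bool),
            )

    def covers_dates(self, dates: Sequence) -> np.ndarray:
        return np.array([_as_date(d) in self._date_index for d in dates])
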