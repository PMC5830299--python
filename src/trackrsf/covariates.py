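"""Habitat covariates for observed and simulated locations.

Covariates per location (distances in km, depth in m, ice in %):

========== ==================================================================
d2coast    distance to the nearest coastline (land-mask boundary)
depth_m    seafloor depth at the containing cell
d21kiso    distance to the 1000 m isobath (shelf break)
d2ice      distance to the same-day ice edge (10% concentration isoline,
           isolines shorter than 50 km discarded)
ice_conc   same-day ice concentration at the containing cell
sea_ice    'yes' if the cell holds any ice, else 'no'
========== ==================================================================

plus derived columns ``sqrt_d2coast``, ``sqrt_depth_m``, ``sqrt_d21kiso``,
``sqrt_d2ice`` and ``ice_conc2`` used by the selection model.

Isolines come from marching squares on the grid (land masked out); distances
are great-circle point-to-polyline, computed by densifying every segment to
at most ``densify_km`` spacing and querying a KD-tree of the densified
vertices embedded on the unit sphere (chord length is monotone in arc length,
so the nearest chord neighbour is the nearest great-circle neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .envstack import EnvStack, _as_date
from .errors import CoverageError
from .geodesy import chord_to_arc_km, haversine_km, unit_vectors
from .tracks import SimTrack, Track

__all__ = [
    "ContourSet",
    "CovariateSampler",
    "extract_contours",
    "distance_to_lines",
    "sample_raster",
    "build_covariate_table",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = [
    "animal_id",
    "replicate",
    "timestamp",
    "case",
    "sex",
    "d2coast",
    "depth_m",
    "d21kiso",
    "d2ice",
    "ice_conc",
    "sea_ice",
    "sqrt_d2coast",
    "sqrt_depth_m",
    "sqrt_d21kiso",
    "sqrt_d2ice",
    "ice_conc2",
]


def polyline_length_km(poly: np.ndarray) -> float:
    """Geodesic length of an (n, 2) lon/lat polyline."""
    if len(poly) < 2:
        return 0.0
    return float(np.sum(haversine_km(poly[:-1, 0], poly[:-1, 1], poly[1:, 0], poly[1:, 1])))


def _densify(poly: np.ndarray, max_km: float) -> np.ndarray:
    """Insert vertices so consecutive spacing is at most ``max_km``.

    Linear interpolation in lon/lat is adequate at <=1 km segment scale.
    """
    out = [poly[:1]]
    for a, b in zip(poly[:-1], poly[1:]):
        d = haversine_km(a[0], a[1], b[0], b[1])
        n = max(int(np.ceil(d / max_km)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a[None, :] * (1 - t) + b[None, :] * t)
    return np.vstack(out)


@dataclass
class ContourSet:
    """Isolines at one level: lon/lat polylines with geodesic lengths."""

    level: float
    polylines: list = field(default_factory=list)
    lengths_km: list = field(default_factory=list)
    _tree: cKDTree | None = field(default=None, repr=False)
    _densify_km: float = field(default=1.0, repr=False)

    def __len__(self) -> int:
        return len(self.polylines)

    @property
    def is_empty(self) -> bool:
        return len(self.polylines) == 0

    def _ensure_tree(self) -> None:
        if self._tree is None and not self.is_empty:
            pts = np.vstack([_densify(p, self._densify_km) for p in self.polylines])
            self._tree = cKDTree(unit_vectors(pts[:, 0], pts[:, 1]))

    def distance_km(self, lon, lat):
        """Great-circle distance (km) from point(s) to the nearest polyline.

        Returns NaN for an empty contour set (undefined distance).
        """
        scalar = np.ndim(lon) == 0
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if self.is_empty:
            out = np.full(lon.shape, np.nan)
        else:
            self._ensure_tree()
            chord, _ = self._tree.query(unit_vectors(lon, lat))
            out = chord_to_arc_km(chord)
        return float(out[0]) if scalar else out


def extract_contours(
    grid: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    level: float,
    min_length_km: float = 0.0,
    land: np.ndarray | None = None,
    densify_km: float = 1.0,
) -> ContourSet:
    """Marching-squares isolines of ``grid`` at ``level``, as lon/lat polylines.

    Land cells (``land`` True) are excluded from contouring. Polylines whose
    geodesic length is below ``min_length_km`` are dropped. A level outside
    the data range yields an empty set.
    """
    grid = np.asarray(grid, dtype=float)
    mask = np.isfinite(grid)
    if land is not None:
        mask &= ~np.asarray(land, dtype=bool)
    raw = measure.find_contours(grid, level=level, mask=mask)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    dlon = lon[1] - lon[0]
    dlat = lat[1] - lat[0]
    polylines, lengths = [], []
    for c in raw:
        poly = np.column_stack((lon[0] + c[:, 1] * dlon, lat[0] + c[:, 0] * dlat))
        length = polyline_length_km(poly)
        if length >= min_length_km and len(poly) >= 2:
            polylines.append(poly)
            lengths.append(length)
    return ContourSet(level=level, polylines=polylines, lengths_km=lengths, _densify_km=densify_km)


def distance_to_lines(lon, lat, contours: ContourSet):
    """Minimum great-circle distance (km) from point(s) to a contour set."""
    return contours.distance_km(lon, lat)


def sample_raster(env: EnvStack, lon, lat, when=None, variable: str = "ice"):
    """Nearest-cell raster value at a location (no interpolation).

    ``variable`` is ``"ice"`` (requires ``when``) or ``"depth"``.
    """
    if variable == "ice":
        if when is None:
            raise ValueError("ice sampling requires a date")
        return env.sample_ice(lon, lat, when)
    if variable == "depth":
        return env.sample_depth(lon, lat)
    raise ValueError(f"unknown variable {variable!r}")


class CovariateSampler:
    """Precomputes contour geometry over an :class:`EnvStack` and evaluates
    the covariate vector at arbitrary locations/dates.

    Ice-edge contour sets (and their KD-trees) are built lazily per date and
    cached; the coastline and the isobath are static.
    """

    def __init__(
        self,
        env: EnvStack,
        ice_edge_level: float = 10.0,
        min_contour_km: float = 50.0,
        isobath_m: float = 1000.0,
        sea_ice_threshold: float = 0.0,
        densify_km: float = 1.0,
    ):
        self.env = env
        self.ice_edge_level = ice_edge_level
        self.min_contour_km = min_contour_km
        self.isobath_m = isobath_m
        self.sea_ice_threshold = sea_ice_threshold
        self.densify_km = densify_km
        self._edge_cache: dict[date, ContourSet] = {}
        # Coastline from the land mask; the 50 km floor applies only to ice edges.
        self.coastline = extract_contours(
            env.land.astype(float), env.lon, env.lat, level=0.5, min_length_km=0.0, densify_km=densify_km
        )
        self.isobath = extract_contours(
            env.depth, env.lon, env.lat, level=isobath_m, min_length_km=0.0, land=env.land, densify_km=densify_km
        )

    def ice_edge(self, when) -> ContourSet:
        d = _as_date(when)
        if d not in self._edge_cache:
            k = self.env.date_layer(d)
            self._edge_cache[d] = extract_contours(
                self.env.ice[k],
                self.env.lon,
                self.env.lat,
                level=self.ice_edge_level,
                min_length_km=self.min_contour_km,
                land=self.env.land,
                densify_km=self.densify_km,
            )
        return self._edge_cache[d]

    def covariates_at(self, lon, lat, when) -> pd.DataFrame:
        """Covariate table for arrays of positions sharing one date."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        env = self.env
        ice = np.atleast_1d(env.sample_ice(lon, lat, when)).astype(float)
        depth = np.atleast_1d(env.sample_depth(lon, lat)).astype(float)
        d2coast = np.atleast_1d(self.coastline.distance_km(lon, lat))
        d21k = np.atleast_1d(self.isobath.distance_km(lon, lat))
        d2ice = np.atleast_1d(self.ice_edge(when).distance_km(lon, lat))
        df = pd.DataFrame(
            {
                "d2coast": d2coast,
                "depth_m": depth,
                "d21kiso": d21k,
                "d2ice": d2ice,
                "ice_conc": ice,
                "sea_ice": np.where(ice > self.sea_ice_threshold, "yes", "no"),
            }
        )
        return add_derived_columns(df)


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    df["sqrt_d2coast"] = np.sqrt(df["d2coast"])
    df["sqrt_depth_m"] = np.sqrt(df["depth_m"])
    df["sqrt_d21kiso"] = np.sqrt(df["d21kiso"])
    df["sqrt_d2ice"] = np.sqrt(df["d2ice"])
    df["ice_conc2"] = df["ice_conc"] ** 2
    return df


def _track_rows(sampler: CovariateSampler, data: pd.DataFrame, animal_id: str, replicate: int, sex) -> pd.DataFrame:
    ts = pd.to_datetime(data["timestamp"])
    days = ts.dt.date
    parts = []
    for d, idx in pd.Series(np.arange(len(data))).groupby(days.values):
        i = idx.values
        cov = sampler.covariates_at(data["lon"].values[i], data["lat"].values[i], d)
        cov.insert(0, "timestamp", ts.values[i])
        parts.append(cov)
    out = pd.concat(parts, ignore_index=True).sort_values("timestamp", kind="stable").reset_index(drop=True)
    out.insert(0, "case", 1 if replicate == 0 else 0)
    out.insert(0, "replicate", replicate)
    out.insert(0, "animal_id", animal_id)
    out.insert(4, "sex", sex)
    return out


def build_covariate_table(
    cases: Sequence[Track],
    controls: Iterable[SimTrack],
    env: EnvStack | CovariateSampler,
    max_missing_fraction: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """One covariate row per location of every case track and control replicate.

    Case rows get ``replicate`` 0 and ``case`` 1; control rows carry their
    replicate index and ``case`` 0. Rows with any missing covariate are
    excluded; their count is reported. Exceeding ``max_missing_fraction``
    missing raises :class:`CoverageError`.

    Returns ``(table, report)``.
    """
    sampler = env if isinstance(env, CovariateSampler) else CovariateSampler(env)
    sex_by_animal = {t.animal_id: t.sex for t in cases}
    parts = [_track_rows(sampler, t.data, t.animal_id, 0, t.sex) for t in cases]
    for s in controls:
        parts.append(_track_rows(sampler, s.data, s.animal_id, s.replicate, sex_by_animal.get(s.animal_id)))
    table = pd.concat(parts, ignore_index=True)
    value_cols = ["d2coast", "depth_m", "d21kiso", "d2ice", "ice_conc"]
    missing = table[value_cols].isna().any(axis=1)
    report = {
        "n_rows": int(len(table)),
        "n_missing_excluded": int(missing.sum()),
        "missing_fraction": float(missing.mean()) if len(table) else 0.0,
    }
    if len(table) and report["missing_fraction"] > max_missing_fraction:
        raise CoverageError(
            f"{report['missing_fraction']:.1%} of rows have missing covariates "
            f"(limit {max_missing_fraction:.1%})"
        )
    table = table.loc[~missing].reset_index(drop=True)
    return table[COVARIATE_COLUMNS], report
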