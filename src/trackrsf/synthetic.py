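"""Synthetic environments, selective tracks, and observation error.

Everything here exists so the full pipeline can be exercised and verified
without external data: an advancing ice field over a shallow shelf, animal
tracks generated with *known* selection strength, and Argos-like location
quality labels and positional noise.

Selection is operationalized as a biased candidate-step walk: at each step,
``n_candidates`` candidate (bearing, speed) draws come from the movement
kernel and one endpoint is chosen with probability proportional to
``exp(truth . x(endpoint))`` where ``x`` holds the same transformed
covariates the inference stage uses. ``n_candidates`` is the knob coupling
the nominal truth coefficients to realized selection: as it grows the
chosen-endpoint distribution approaches the exponentially weighted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .covariates import CovariateSampler
from .envstack import EnvStack
from .errors import InvalidConfigError, StepGenerationError
from .fixtures import table1_fixture  # re-exported: in-package metadata fixture
from .geodesy import destination_point
from .rsf import INTERACTIONS, SINGLE_EFFECTS, ModelFormula, design_matrix
from .tracks import LQ_CLASSES, Track

__all__ = [
    "EnvConfig",
    "MovementParams",
    "TruthRSF",
    "make_environment",
    "make_selective_tracks",
    "add_argos_error",
    "table1_fixture",
    "DEFAULT_ARGOS_SD_KM",
]

#: km per degree of latitude on the working sphere.
DEG_KM = 111.195

#: Isotropic per-class Argos error scales (km). Conventional defaults; the
#: class system itself does not publish magnitudes.
DEFAULT_ARGOS_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 8.0, "B": 15.0}


@dataclass
class EnvConfig:
    """Geometry and dynamics of the synthetic environment.

    The ice field is a monotone north-to-south concentration ramp whose 10%
    level advances southward at ``ice_advance_km_per_day``; bathymetry is a
    shallow shelf with a monotone southward slope crossing 1000 m; land is
    everything east of ``coast_lon`` (set to None for an all-sea domain).
    """

    lon_min: float = -176.0
    lon_max: float = -160.0
    lat_min: float = 56.0
    lat_max: float = 67.5
    cell_deg: float = 0.1
    n_days: int = 150
    start_date: date = date(2005, 11, 1)
    ice_advance_km_per_day: float = 4.0
    ice_gradient_km: float = 400.0
    max_conc: float = 95.0
    edge_start_lat: float = 66.0
    shelf_depth_m: float = 60.0
    slope_lat: float = 58.5
    slope_width_km: float = 150.0
    max_depth_m: float = 3200.0
    coast_lon: float | None = -161.0
    seed: int = 0

    def validate(self) -> None:
        if self.cell_deg <= 0:
            raise InvalidConfigError("cell_deg must be > 0")
        if self.n_days < 1:
            raise InvalidConfigError("n_days must be >= 1")
        if self.max_conc < 0 or self.max_conc > 100:
            raise InvalidConfigError("max_conc must be in [0, 100]")
        nlon = int(round((self.lon_max - self.lon_min) / self.cell_deg))
        nlat = int(round((self.lat_max - self.lat_min) / self.cell_deg))
        if nlon <= 1 or nlat <= 1:
            raise InvalidConfigError("degenerate extent: need more than one cell per axis")


def make_environment(cfg: EnvConfig) -> EnvStack:
    """Deterministic synthetic ice + bathymetry stack from a config."""
    cfg.validate()
    nlon = int(round((cfg.lon_max - cfg.lon_min) / cfg.cell_deg))
    nlat = int(round((cfg.lat_max - cfg.lat_min) / cfg.cell_deg))
    lon = cfg.lon_min + (np.arange(nlon) + 0.5) * cfg.cell_deg
    lat = cfg.lat_min + (np.arange(nlat) + 0.5) * cfg.cell_deg
    lon2d, lat2d = np.meshgrid(lon, lat)

    land = np.zeros((nlat, nlon), dtype=bool)
    if cfg.coast_lon is not None:
        land = lon2d >= cfg.coast_lon

    depth = cfg.shelf_depth_m + (cfg.max_depth_m - cfg.shelf_depth_m) * np.clip(
        (cfg.slope_lat - lat2d) * DEG_KM / cfg.slope_width_km, 0.0, 1.0
    )
    depth[land] = np.nan

    dates = [cfg.start_date + timedelta(days=int(k)) for k in range(cfg.n_days)]
    ice = np.empty((cfg.n_days, nlat, nlon))
    # place the ramp so concentration == 10% exactly at the advancing edge latitude
    for k in range(cfg.n_days):
        edge_lat = cfg.edge_start_lat - cfg.ice_advance_km_per_day * k / DEG_KM
        lat_zero = edge_lat - (10.0 / max(cfg.max_conc, 1e-9)) * cfg.ice_gradient_km / DEG_KM
        conc = np.clip((lat2d - lat_zero) * DEG_KM / cfg.ice_gradient_km * cfg.max_conc, 0.0, cfg.max_conc)
        conc[land] = np.nan
        ice[k] = conc
    return EnvStack(lon=lon, lat=lat, dates=dates, ice=ice, depth=depth, land=land)


@dataclass
class MovementParams:
    """Step kernel for track generation: speeds and bearing persistence.

    Each bearing is a normal perturbation around a mixture of the previous
    bearing and a fixed drift direction (default due south), giving a
    correlated walk with a configurable seasonal drift.
    """

    mean_speed_kmh: float = 2.0
    speed_sd_kmh: float = 1.0
    max_speed_kmh: float = 8.0
    bearing_sd_deg: float = 40.0
    drift_bearing_deg: float = 180.0
    drift_weight: float = 0.3

    def sample_speed(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        s = np.abs(rng.normal(self.mean_speed_kmh, self.speed_sd_kmh, size=n))
        return np.clip(s, 0.0, self.max_speed_kmh)

    def sample_bearing(self, rng: np.random.Generator, prev: float | None, n: int = 1) -> np.ndarray:
        if prev is None:
            mu = self.drift_bearing_deg
        else:
            v_prev = np.array([np.sin(np.radians(prev)), np.cos(np.radians(prev))])
            v_drift = np.array(
                [np.sin(np.radians(self.drift_bearing_deg)), np.cos(np.radians(self.drift_bearing_deg))]
            )
            v = (1.0 - self.drift_weight) * v_prev + self.drift_weight * v_drift
            mu = np.degrees(np.arctan2(v[0], v[1]))
        return (rng.normal(mu, self.bearing_sd_deg, size=n)) % 360.0


@dataclass
class TruthRSF:
    """Ground-truth selection coefficients on the inference term vocabulary."""

    coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        vocab = set(SINGLE_EFFECTS) | set(INTERACTIONS)
        unknown = [k for k in self.coefficients if k not in vocab]
        if unknown:
            raise InvalidConfigError(f"truth coefficients outside model vocabulary: {unknown}")

    @property
    def active_terms(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]

    def formula(self) -> ModelFormula | None:
        terms = self.active_terms
        if not terms:
            return None
        need = set(terms)
        for t in terms:
            need.update(t.split(":"))
        if "ice_conc2" in need:
            need.add("ice_conc")
        ordered = [t for t in SINGLE_EFFECTS + INTERACTIONS if t in need]
        return ModelFormula(terms=ordered)


def _candidate_weights(
    sampler: CovariateSampler, truth: TruthRSF, lons, lats, when, sex: str
) -> np.ndarray:
    formula = truth.formula()
    if formula is None:
        return np.zeros(len(lons))
    cov = sampler.covariates_at(lons, lats, when)
    cov["sex"] = sex
    X = design_matrix(cov, formula)
    logw = np.zeros(len(cov))
    for t, b in truth.coefficients.items():
        if b != 0.0:
            logw += b * X[t].values
    return logw


def make_selective_tracks(
    env: EnvStack,
    truth: TruthRSF,
    move: MovementParams,
    n_animals: int,
    seed: int,
    n_steps: int = 200,
    n_candidates: int = 20,
    mean_gap_hours: float = 6.0,
    gap_jitter_hours: float = 2.0,
    start_lonlat: tuple[float, float] | None = None,
    start_time: datetime | None = None,
    max_retries: int = 50,
    sampler: CovariateSampler | None = None,
) -> list[Track]:
    """Generate ``n_animals`` tracks with known selection over ``env``.

    Timestamps are irregular (uniform jitter around ``mean_gap_hours``);
    candidates landing on land or off-grid are discarded and the whole
    candidate set redrawn up to ``max_retries`` times before a
    :class:`StepGenerationError` naming the animal and time. Deterministic
    for a fixed seed. Sexes alternate F, M, F, ...
    """
    if n_candidates < 1:
        raise InvalidConfigError("n_candidates must be >= 1")
    if sampler is None:
        sampler = CovariateSampler(env)
    if start_time is None:
        start_time = datetime.combine(env.dates[0], datetime.min.time()) + timedelta(hours=12)
    if start_lonlat is None:
        lon0 = float(env.lon[len(env.lon) // 3])
        lat0 = float(env.lat[int(len(env.lat) * 0.85)])
    else:
        lon0, lat0 = start_lonlat
    weighted = truth.formula() is not None
    tracks = []
    for a in range(n_animals):
        rng = np.random.default_rng([seed, a])
        sex = "F" if a % 2 == 0 else "M"
        times = [start_time]
        lons = [lon0]
        lats = [lat0]
        t = start_time
        prev_bearing: float | None = None
        for k in range(n_steps):
            gap = max(0.5, mean_gap_hours + rng.uniform(-gap_jitter_hours, gap_jitter_hours))
            t = t + timedelta(hours=gap)
            for attempt in range(max_retries + 1):
                brgs = move.sample_bearing(rng, prev_bearing, n=n_candidates)
                spds = move.sample_speed(rng, n=n_candidates)
                clon, clat = destination_point(lons[-1], lats[-1], brgs, spds * gap)
                clon, clat = np.atleast_1d(clon), np.atleast_1d(clat)
                ok = env.in_extent(clon, clat)
                if np.any(ok):
                    ok = ok & ~np.array(
                        [env.is_land(x, y) if o else True for x, y, o in zip(clon, clat, ok)]
                    )
                if np.any(ok):
                    valid = np.flatnonzero(ok)
                    if weighted and valid.size > 1:
                        logw = _candidate_weights(
                            sampler, truth, clon[valid], clat[valid], t.date(), sex
                        )
                        w = np.exp(logw - logw.max())
                        w /= w.sum()
                        pick = valid[rng.choice(valid.size, p=w)]
                    elif valid.size > 1:
                        pick = valid[rng.integers(valid.size)]
                    else:
                        pick = valid[0]
                    lons.append(float(clon[pick]))
                    lats.append(float(clat[pick]))
                    times.append(t)
                    prev_bearing = float(brgs[pick])
                    break
            else:
                raise StepGenerationError(
                    f"animal a{a}: all {n_candidates} candidates on land/off-grid "
                    f"after {max_retries} retries at {t.isoformat()}"
                )
        tracks.append(
            Track(
                animal_id=f"a{a}",
                sex=sex,
                data=pd.DataFrame({"timestamp": times, "lon": lons, "lat": lats}),
            )
        )
    return tracks


def sample_sea_points(
    env: EnvStack, n: int, rng: np.random.Generator, max_tries: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random sea locations within the grid extent."""
    le, la = env.lon_edges, env.lat_edges
    lons = np.empty(0)
    lats = np.empty(0)
    for _ in range(max_tries):
        need = n - lons.size
        if need <= 0:
            break
        cl = rng.uniform(le[0], le[-1] - 1e-9, size=2 * need)
        ca = rng.uniform(la[0], la[-1] - 1e-9, size=2 * need)
        sea = ~np.atleast_1d(env.is_land(cl, ca))
        lons = np.concatenate((lons, cl[sea]))
        lats = np.concatenate((lats, ca[sea]))
    if lons.size < n:
        raise StepGenerationError("could not find enough sea cells in the environment")
    return lons[:n], lats[:n]


def make_selective_rows(
    env: EnvStack,
    truth: TruthRSF,
    n_case: int,
    n_rep: int,
    seed: int,
    n_candidates: int = 20,
    n_dates: int = 10,
    sampler: CovariateSampler | None = None,
    sex: str = "F",
) -> pd.DataFrame:
    """Independent case/control covariate rows with known selection.

    Unlike :func:`make_selective_tracks` this draws every row independently
    from a shared availability pool (uniform sea locations on a handful of
    environment dates): each case row picks one of ``n_candidates``
    availability draws with probability proportional to
    ``exp(truth . x)``, and each of the ``n_rep`` control replicates is an
    unweighted draw from the same pool. The logistic contrast between case
    and control rows then targets the truth coefficients directly (up to
    the 1 - 1/n_candidates finite-candidate attenuation), which is what the
    calibration and recovery properties exercise.
    """
    if sampler is None:
        sampler = CovariateSampler(env)
    rng = np.random.default_rng([seed, 11])
    dates = [env.dates[i] for i in rng.choice(len(env.dates), size=min(n_dates, len(env.dates)), replace=False)]
    formula = truth.formula()

    def rows_for(case: bool, replicate: int, rng: np.random.Generator) -> pd.DataFrame:
        m = n_candidates if case and formula is not None else 1
        parts = []
        per_date = np.array_split(np.arange(n_case), len(dates))
        for di, idx in enumerate(per_date):
            if idx.size == 0:
                continue
            when = dates[di]
            lons, lats = sample_sea_points(env, idx.size * m, rng)
            cov = sampler.covariates_at(lons, lats, when)
            cov["sex"] = sex
            if m > 1:
                X = design_matrix(cov, formula)
                logw = np.zeros(len(cov))
                for t, b in truth.coefficients.items():
                    if b != 0.0:
                        logw += b * X[t].values
                logw = logw.reshape(idx.size, m)
                gumbel = rng.gumbel(size=logw.shape)
                pick = (logw + gumbel).argmax(axis=1) + np.arange(idx.size) * m
                cov = cov.iloc[pick]
            cov = cov.copy()
            cov.insert(0, "timestamp", pd.Timestamp(when))
            parts.append(cov)
        out = pd.concat(parts, ignore_index=True)
        out.insert(0, "case", 1 if case else 0)
        out.insert(0, "replicate", replicate)
        out.insert(0, "animal_id", "iid")
        out.insert(4, "sex", out.pop("sex"))
        return out

    tables = [rows_for(True, 0, np.random.default_rng([seed, 13]))]
    for r in range(1, n_rep + 1):
        tables.append(rows_for(False, r, np.random.default_rng([seed, 17, r])))
    return pd.concat(tables, ignore_index=True)


def add_argos_error(
    track: Track,
    class_mix: dict | None = None,
    class_sd_km: dict | None = None,
    seed: int = 0,
) -> Track:
    """Attach LQ labels and isotropic Gaussian position noise to a track.

    ``class_mix`` gives proportions over the classes {3,2,1,0,A,B} (must sum
    to 1); ``class_sd_km`` the per-class noise scale. True positions are
    retained in ``true_lon``/``true_lat`` for diagnostics.
    """
    class_mix = class_mix or {"3": 0.1, "2": 0.15, "1": 0.2, "0": 0.25, "A": 0.2, "B": 0.1}
    class_sd_km = {**DEFAULT_ARGOS_SD_KM, **(class_sd_km or {})}
    classes = list(class_mix.keys())
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise InvalidConfigError(f"class proportions sum to {probs.sum()}, expected 1")
    bad = [c for c in classes if c not in LQ_CLASSES]
    if bad:
        raise InvalidConfigError(f"unknown LQ classes: {bad}")
    if any(class_sd_km.get(c, 0.0) < 0 for c in classes):
        raise InvalidConfigError("negative class sd")
    rng = np.random.default_rng([seed, 97])
    n = len(track)
    lq = rng.choice(classes, size=n, p=probs)
    sd = np.array([class_sd_km.get(c, 0.0) for c in lq])
    dx = rng.normal(0.0, 1.0, size=n) * sd
    dy = rng.normal(0.0, 1.0, size=n) * sd
    lat = track.data["lat"].values
    lon = track.data["lon"].values
    new = track.data.copy()
    new["true_lon"] = lon
    new["true_lat"] = lat
    new["lat"] = lat + dy / DEG_KM
    new["lon"] = lon + dx / (DEG_KM * np.cos(np.radians(lat)))
    new["lq"] = lq
    return Track(animal_id=track.animal_id, sex=track.sex, data=new)
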