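"""Null movement model: step decomposition, transition-table fit, simulation.

The null model is a first-order correlated random walk on absolute bearing
bins plus an independent speed distribution on a variance-stabilized scale.
Simulated control tracks reproduce the template track's timestamps exactly:
each inter-fix interval becomes a single draw of (bearing, speed) and the
walker advances speed x elapsed along the geodesic.

Speeds are capped and modelled on a fourth-root scale before binning:
positioning error inflates apparent speed over short intervals and badly
skews the raw distribution, so the fit bins a tamed quantity and sampling
inverts the transform.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .envstack import EnvStack
from .errors import DegenerateDataError, InsufficientDataError, SimulationStuckError
from .geodesy import destination_point, haversine_km, initial_bearing_deg
from .tracks import SimTrack, Track

__all__ = [
    "MovementFitConfig",
    "MovementModel",
    "decompose_steps",
    "fit_movement_model",
    "simulate_track",
    "simulate_ensemble",
]

STEP_COLUMNS = ["animal_id", "t0", "t1", "elapsed_h", "bearing", "speed_kmh", "length_km"]


def decompose_steps(track: Track) -> pd.DataFrame:
    """Sequential movement vectors: one row per consecutive fix pair.

    Columns: ``animal_id, t0, t1, elapsed_h, bearing, speed_kmh, length_km``.
    Bearing is the initial forward azimuth; length the great-circle distance;
    a zero-length step has bearing 0 by convention.
    """
    if len(track) < 2:
        raise InsufficientDataError(f"track {track.animal_id}: need >= 2 locations, have {len(track)}")
    d = track.data
    lon0, lat0 = d["lon"].values[:-1], d["lat"].values[:-1]
    lon1, lat1 = d["lon"].values[1:], d["lat"].values[1:]
    t0 = d["timestamp"].values[:-1]
    t1 = d["timestamp"].values[1:]
    elapsed = (t1 - t0) / np.timedelta64(1, "h")
    length = haversine_km(lon0, lat0, lon1, lat1)
    bearing = np.atleast_1d(initial_bearing_deg(lon0, lat0, lon1, lat1))
    return pd.DataFrame(
        {
            "animal_id": track.animal_id,
            "t0": t0,
            "t1": t1,
            "elapsed_h": elapsed,
            "bearing": bearing,
            "speed_kmh": length / elapsed,
            "length_km": length,
        }
    )


@dataclass
class MovementFitConfig:
    n_bearing_bins: int = 36
    n_speed_bins: int = 20
    max_speed_kmh: float = 8.0
    transform: str = "fourth_root"  # or "identity"
    smoothing: float = 0.5  # additive (pseudo-count) smoothing per cell
    min_steps: int = 100
    max_gap_hours: float = 72.0
    condition_speed_on_previous: bool = False


def _transform(x: np.ndarray, spec: str) -> np.ndarray:
    if spec == "fourth_root":
        return np.asarray(x, dtype=float) ** 0.25
    if spec == "identity":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown transform {spec!r}")


def _inverse(u: np.ndarray, spec: str) -> np.ndarray:
    if spec == "fourth_root":
        return np.asarray(u, dtype=float) ** 4
    return np.asarray(u, dtype=float)


@dataclass
class MovementModel:
    """Fitted transition tables for bearing and speed.

    ``bearing_trans[i, j]`` is P(current bearing in bin j | previous in bin i);
    rows sum to one. Speed probabilities live on the transformed scale between
    ``speed_edges`` (``(S,)`` marginal or ``(S, S)`` conditional).
    """

    bearing_edges: np.ndarray
    bearing_trans: np.ndarray
    bearing_marginal: np.ndarray
    speed_edges: np.ndarray
    speed_probs: np.ndarray
    transform: str
    max_speed_kmh: float
    conditional_speed: bool = False
    meta: dict = field(default_factory=dict)

    def bearing_bin(self, bearing) -> np.ndarray:
        idx = np.digitize(np.asarray(bearing) % 360.0, self.bearing_edges) - 1
        return np.clip(idx, 0, len(self.bearing_edges) - 2)

    def speed_bin(self, speed) -> np.ndarray:
        u = _transform(np.clip(speed, 0.0, self.max_speed_kmh), self.transform)
        idx = np.digitize(u, self.speed_edges) - 1
        return np.clip(idx, 0, len(self.speed_edges) - 2)

    def sample_bearing(self, rng: np.random.Generator, prev_bin: int | None = None) -> tuple[float, int]:
        p = self.bearing_marginal if prev_bin is None else self.bearing_trans[prev_bin]
        j = rng.choice(len(p), p=p)
        b = rng.uniform(self.bearing_edges[j], self.bearing_edges[j + 1])
        return float(b), int(j)

    def sample_speed(self, rng: np.random.Generator, prev_bin: int | None = None) -> tuple[float, int]:
        if self.conditional_speed and prev_bin is not None:
            p = self.speed_probs[prev_bin]
        else:
            p = self.speed_probs if self.speed_probs.ndim == 1 else self.speed_probs.mean(axis=0)
        j = rng.choice(len(p), p=p)
        u = rng.uniform(self.speed_edges[j], self.speed_edges[j + 1])
        return float(_inverse(u, self.transform)), int(j)

    def to_dict(self) -> dict:
        return {
            "bearing_edges": self.bearing_edges.tolist(),
            "bearing_trans": self.bearing_trans.tolist(),
            "bearing_marginal": self.bearing_marginal.tolist(),
            "speed_edges": self.speed_edges.tolist(),
            "speed_probs": self.speed_probs.tolist(),
            "transform": self.transform,
            "max_speed_kmh": self.max_speed_kmh,
            "conditional_speed": self.conditional_speed,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MovementModel":
        return cls(
            bearing_edges=np.asarray(d["bearing_edges"]),
            bearing_trans=np.asarray(d["bearing_trans"]),
            bearing_marginal=np.asarray(d["bearing_marginal"]),
            speed_edges=np.asarray(d["speed_edges"]),
            speed_probs=np.asarray(d["speed_probs"]),
            transform=d["transform"],
            max_speed_kmh=d["max_speed_kmh"],
            conditional_speed=d.get("conditional_speed", False),
            meta=d.get("meta", {}),
        )


def fit_movement_model(steps: pd.DataFrame, cfg: MovementFitConfig | None = None) -> MovementModel:
    """Estimate bearing-transition and speed tables from pooled steps.

    Steps with elapsed time above ``cfg.max_gap_hours`` are excluded from the
    fit (their intervals are still simulated as single draws downstream).
    Tables use additive smoothing so no transition row is degenerate.
    """
    cfg = cfg or MovementFitConfig()
    steps = steps.loc[(steps["elapsed_h"] > 0) & (steps["elapsed_h"] <= cfg.max_gap_hours)]
    if len(steps) < cfg.min_steps:
        raise InsufficientDataError(f"{len(steps)} usable steps < required {cfg.min_steps}")
    speeds = np.clip(steps["speed_kmh"].values, 0.0, cfg.max_speed_kmh)
    if np.all(speeds == 0):
        raise DegenerateDataError("all step speeds are zero")

    B = cfg.n_bearing_bins
    bearing_edges = np.linspace(0.0, 360.0, B + 1)
    bbin = np.clip(np.digitize(steps["bearing"].values % 360.0, bearing_edges) - 1, 0, B - 1)
    counts = np.full((B, B), cfg.smoothing)
    marg = np.full(B, cfg.smoothing)
    np.add.at(marg, bbin, 1.0)
    # transitions only across contiguous step pairs within an animal
    for _, grp in steps.groupby("animal_id", sort=False):
        gb = np.clip(np.digitize(grp["bearing"].values % 360.0, bearing_edges) - 1, 0, B - 1)
        contiguous = grp["t0"].values[1:] == grp["t1"].values[:-1]
        np.add.at(counts, (gb[:-1][contiguous], gb[1:][contiguous]), 1.0)
    bearing_trans = counts / counts.sum(axis=1, keepdims=True)
    bearing_marginal = marg / marg.sum()

    S = cfg.n_speed_bins
    u = _transform(speeds, cfg.transform)
    speed_edges = np.linspace(0.0, _transform(np.array(cfg.max_speed_kmh), cfg.transform), S + 1)
    sbin = np.clip(np.digitize(u, speed_edges) - 1, 0, S - 1)
    if cfg.condition_speed_on_previous:
        sc = np.full((S, S), cfg.smoothing)
        for _, grp in steps.groupby("animal_id", sort=False):
            gu = _transform(np.clip(grp["speed_kmh"].values, 0.0, cfg.max_speed_kmh), cfg.transform)
            gs = np.clip(np.digitize(gu, speed_edges) - 1, 0, S - 1)
            contiguous = grp["t0"].values[1:] == grp["t1"].values[:-1]
            np.add.at(sc, (gs[:-1][contiguous], gs[1:][contiguous]), 1.0)
        speed_probs = sc / sc.sum(axis=1, keepdims=True)
    else:
        sp = np.full(S, cfg.smoothing)
        np.add.at(sp, sbin, 1.0)
        speed_probs = sp / sp.sum()

    return MovementModel(
        bearing_edges=bearing_edges,
        bearing_trans=bearing_trans,
        bearing_marginal=bearing_marginal,
        speed_edges=speed_edges,
        speed_probs=speed_probs,
        transform=cfg.transform,
        max_speed_kmh=cfg.max_speed_kmh,
        conditional_speed=cfg.condition_speed_on_previous,
        meta={"n_steps": int(len(steps)), "n_animals": int(steps["animal_id"].nunique())},
    )


def _rng_for(seed: int, replicate: int, animal_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, replicate, zlib.crc32(str(animal_id).encode())])


def simulate_track(
    model: MovementModel,
    template: Track,
    env: EnvStack,
    replicate: int,
    seed: int,
    max_retries: int = 50,
) -> SimTrack:
    """One control track matched to ``template``'s timestamps.

    Starts at the template's first fix; each interval advances by one
    (bearing, speed) draw. Draws landing on land (or off-grid) are rejected
    and redrawn up to ``max_retries`` times, after which a
    :class:`SimulationStuckError` identifies the animal and timestamp.
    """
    if len(template) < 2:
        raise InsufficientDataError(f"template {template.animal_id}: need >= 2 locations")
    rng = _rng_for(seed, replicate, template.animal_id)
    ts = template.data["timestamp"].reset_index(drop=True)
    lon = np.empty(len(ts))
    lat = np.empty(len(ts))
    lon[0] = template.data["lon"].iloc[0]
    lat[0] = template.data["lat"].iloc[0]
    elapsed = (ts.values[1:] - ts.values[:-1]) / np.timedelta64(1, "h")
    prev_bbin: int | None = None
    prev_sbin: int | None = None
    for i, dt_h in enumerate(elapsed):
        for attempt in range(max_retries + 1):
            b, bbin = model.sample_bearing(rng, prev_bbin)
            s, sbin = model.sample_speed(rng, prev_sbin)
            nlon, nlat = destination_point(lon[i], lat[i], b, s * dt_h)
            if env.in_extent(nlon, nlat) and not env.is_land(nlon, nlat):
                lon[i + 1], lat[i + 1] = nlon, nlat
                prev_bbin, prev_sbin = bbin, sbin
                break
        else:
            raise SimulationStuckError(
                f"animal {template.animal_id} replicate {replicate}: no sea destination "
                f"after {max_retries} retries at {ts.iloc[i + 1]}"
            )
    return SimTrack(
        animal_id=template.animal_id,
        replicate=replicate,
        data=pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat}),
    )


def simulate_ensemble(
    model: MovementModel,
    tracks: Sequence[Track],
    env: EnvStack,
    n_rep: int = 20,
    seed: int = 0,
    max_retries: int = 50,
) -> list[SimTrack]:
    """``n_rep`` control tracks per template, replicate-indexed seeds."""
    out = []
    for template in tracks:
        for rep in range(1, n_rep + 1):
            out.append(simulate_track(model, template, env, rep, seed, max_retries=max_retries))
    return out
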