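"""Track containers shared by ingest, simulation, and covariate stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import OrderingError

__all__ = ["Track", "SimTrack", "LQ_CLASSES", "LQ_KEEP"]

#: The closed set of Argos location-quality classes.
LQ_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
#: Classes retained by quality filtering (worst classes B and Z dropped).
LQ_KEEP = ("3", "2", "1", "0", "A")


def _check_monotone(ts: pd.Series, label: str) -> None:
    if len(ts) >= 2 and not ts.is_monotonic_increasing:
        raise OrderingError(f"{label}: timestamps are not non-decreasing")
    if len(ts) >= 2 and ts.duplicated().any():
        raise OrderingError(f"{label}: duplicate timestamps present")


@dataclass
class Track:
    """An observed animal track: ordered, timestamped positions.

    ``data`` columns: ``timestamp`` (datetime64), ``lon``, ``lat`` in degrees,
    and optionally ``lq``. Timestamps are strictly increasing.
    """

    animal_id: str
    data: pd.DataFrame
    sex: str | None = None

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        if len(self.data):
            self.data["timestamp"] = pd.to_datetime(self.data["timestamp"])
            _check_monotone(self.data["timestamp"], f"track {self.animal_id}")
            lon = self.data["lon"].astype(float)
            self.data["lon"] = ((lon + 180.0) % 360.0) - 180.0
            self.data.loc[self.data["lon"] == -180.0, "lon"] = 180.0

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]


@dataclass
class SimTrack:
    """A simulated control track temporally matched to a template ``Track``."""

    animal_id: str
    replicate: int
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        if len(self.data):
            self.data["timestamp"] = pd.to_datetime(self.data["timestamp"])
            _check_monotone(self.data["timestamp"], f"simtrack {self.animal_id}/{self.replicate}")

    def __len__(self) -> int:
        return len(self.data)
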