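"""Packaged reference tables used by tests and the acceptance report.

``table1_fixture`` is the deployment-metadata table for the 26 tagged
animals (ids, sex, dates, record durations, analysis-inclusion marks), with
dates stored as ISO strings. ``final_model_fixture`` holds the published
final selection-model coefficients used for desk-scale checks such as the
quadratic ice-concentration optimum.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["table1_fixture", "final_model_fixture"]

_DATE_COLS = ["date_captured", "date_entered_bering", "date_last_location"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("trackrsf.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def table1_fixture() -> pd.DataFrame:
    """The 26-row deployment metadata table, one row per tagged animal."""
    df = _read("table1.csv")
    df["sdr_id"] = df["sdr_id"].astype(str)
    for c in _DATE_COLS:
        df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
    df["used_in_habitat"] = df["used_in_habitat"].astype(bool)
    return df


def final_model_fixture() -> pd.DataFrame:
    """Published final-model terms with estimates, SEs, z and p values."""
    return _read("final_model.csv")
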