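"""Reading, aggregating and completing AQI panels.

The downstream correlation network requires a complete date × site matrix
of daily mean AQI. This module reads the two input tables (a site table
with coordinates and a long-format readings table), averages hourly
readings to daily means, and fills the remaining gaps: a single missing
day becomes the mean of its two neighbours, longer interior gaps are
linearly interpolated between the flanking observed days, and gaps at the
series ends take the nearest observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "SitesTable",
    "ReadingsPanel",
    "read_sites",
    "read_readings",
    "aggregate_daily",
    "impute_missing",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SitesTable:
    """Monitoring sites: identity, display name, WGS-84 coordinates.

    Row order is the canonical node order of every downstream matrix and
    network. ``category`` is an optional free label (e.g. Urban/Suburban).
    """

    frame: pd.DataFrame  # columns: site_id, name, latitude, longitude[, category]

    def __post_init__(self) -> None:
        df = self.frame
        required = {"site_id", "latitude", "longitude"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sites table missing columns: {sorted(missing)}")
        if len(df) < 2:
            raise ValueError("need >= 2 sites to build a network")
        dup = df["site_id"][df["site_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate site_id: {dup.iloc[0]!r}")
        for row, (lat, lon) in enumerate(zip(df["latitude"], df["longitude"])):
            if not -90.0 <= lat <= 90.0:
                raise ValueError(f"row {row}: latitude {lat} outside [-90, 90]")
            if not -180.0 <= lon <= 180.0:
                raise ValueError(f"row {row}: longitude {lon} outside [-180, 180]")

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame["site_id"])

    @property
    def latitudes(self) -> np.ndarray:
        return self.frame["latitude"].to_numpy(dtype=float)

    @property
    def longitudes(self) -> np.ndarray:
        return self.frame["longitude"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: PathLike) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ReadingsPanel:
    """Time × site grid of AQI values.

    ``frequency`` is ``"hourly"`` or ``"daily"``. After preprocessing
    (``aggregate_daily`` then ``impute_missing``) a daily panel is complete:
    contiguous calendar dates and no missing cells.
    """

    values: pd.DataFrame  # index: DatetimeIndex, columns: site ids
    frequency: str = "daily"
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if self.frequency not in ("hourly", "daily"):
            raise ValueError(f"unknown frequency {self.frequency!r}")
        if not isinstance(self.values.index, pd.DatetimeIndex):
            self.values = self.values.copy()
            self.values.index = pd.DatetimeIndex(self.values.index)
        self.values = self.values.sort_index()
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative AQI values are invalid")

    @property
    def sites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_complete(self) -> bool:
        if self.values.isna().any().any():
            return False
        if self.frequency == "daily" and len(self.values) > 1:
            full = pd.date_range(self.values.index[0], self.values.index[-1], freq="D")
            return self.values.index.equals(full)
        return True

    def to_csv(self, path: PathLike) -> None:
        out = self.values.copy()
        out.index.name = "date" if self.frequency == "daily" else "timestamp"
        out.to_csv(path)


def read_sites(path: PathLike) -> SitesTable:
    """Read a sites CSV (header ``site_id,name,latitude,longitude[,category]``)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    if "name" not in df.columns:
        df["name"] = df["site_id"]
    cols = ["site_id", "name", "latitude", "longitude"]
    if "category" in df.columns:
        cols.append("category")
    return SitesTable(df[cols].reset_index(drop=True))


def read_readings(
    path: PathLike,
    frequency: str = "daily",
    sites: Optional[SitesTable] = None,
) -> ReadingsPanel:
    """Read long-format readings (``site_id,timestamp,aqi`` or ``site_id,date,aqi``).

    Rows are pivoted to a time × site panel (possibly incomplete). If a
    ``sites`` table is given, readings for unknown site ids are a hard
    error. Duplicate (site, timestamp) rows and negative AQI values are
    rejected.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    time_col = "timestamp" if "timestamp" in df.columns else "date"
    if time_col not in df.columns:
        raise ValueError("readings file needs a 'timestamp' or 'date' column")
    value_col = "aqi" if "aqi" in df.columns else "value"
    if value_col not in df.columns:
        raise ValueError("readings file needs an 'aqi' or 'value' column")

    df[time_col] = pd.to_datetime(df[time_col])
    if sites is not None:
        unknown = set(df["site_id"]) - set(sites.site_ids)
        if unknown:
            raise ValueError(f"readings reference unknown site ids: {sorted(unknown)}")
    dup = df.duplicated(subset=["site_id", time_col])
    if dup.any():
        bad = df.loc[dup, ["site_id", time_col]].iloc[0]
        raise ValueError(
            f"duplicate reading for site {bad['site_id']!r} at {bad[time_col]}"
        )
    if (df[value_col] < 0).any():
        raise ValueError("negative AQI values are invalid")

    panel = df.pivot(index=time_col, columns="site_id", values=value_col)
    panel.columns.name = None
    if sites is not None:
        # canonical node order; sites with no readings appear as all-NaN columns
        panel = panel.reindex(columns=sites.site_ids)
    return ReadingsPanel(panel, frequency=frequency)


def aggregate_daily(panel: ReadingsPanel, min_hours: int = 1) -> ReadingsPanel:
    """Average an hourly panel to daily means.

    A (site, day) cell with fewer than ``min_hours`` observed hours is left
    missing, to be handled by :func:`impute_missing`.
    """
    if panel.frequency != "hourly":
        raise ValueError("aggregate_daily expects an hourly panel")
    if min_hours < 1:
        raise ValueError("min_hours must be >= 1")
    grouped = panel.values.groupby(panel.values.index.normalize())
    means = grouped.mean()
    counts = grouped.count()
    means = means.where(counts >= min_hours)
    # make the date axis contiguous; fully unobserved days appear as NaN rows
    if len(means) > 1:
        full = pd.date_range(means.index[0], means.index[-1], freq="D")
        means = means.reindex(full)
    return ReadingsPanel(means, frequency="daily")


def impute_missing(panel: ReadingsPanel) -> ReadingsPanel:
    """Fill every gap in a daily panel.

    Single-day interior gaps become the mean of the previous and next
    observed day; multi-day interior gaps are linearly interpolated between
    the flanking observed days (the same rule, applied proportionally);
    leading/trailing gaps take the nearest observed value. The number of
    filled cells is reported on the result (``n_imputed``).
    """
    if panel.frequency != "daily":
        raise ValueError("impute_missing expects a daily panel")
    values = panel.values
    empty = values.columns[values.isna().all()]
    if len(empty) > 0:
        raise ValueError(f"site {empty[0]!r} has no observed values")
    n_missing = int(values.isna().to_numpy().sum())
    filled = values.interpolate(method="time", limit_direction="both", axis=0)
    return ReadingsPanel(filled, frequency="daily", n_imputed=n_missing)
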