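"""Readers and writers for dive telemetry tables.

All files are plain CSV with a mandatory header row, comma separators,
decimal points and ISO 8601 UTC timestamps.  Lines starting with ``#`` are
treated as provenance comments and skipped on read.

Two table dialects exist for abstracted dives: the ``seconds`` dialect
stores the four at-depth inflection times as seconds from the dive start,
while the ``percent`` dialect (the convention used by satellite-relay data
loggers, which transmit inflection times as proportions of dive duration)
stores them as percentages of the dive duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("driftdive")

ABSTRACTED_COLUMNS = [
    "individual_id", "dive_id", "start_utc", "duration_s",
    "d1_m", "d2_m", "d3_m", "d4_m", "t1", "t2", "t3", "t4",
    "lon", "lat",
]

DRIFT_SERIES_COLUMNS = ["individual_id", "timestamp_utc", "drift_rate_ms", "dive_id"]

LABEL_COLUMNS = [
    "dive_id", "individual_id", "dive_type", "true_drift_rate",
    "drift_start_s", "drift_end_s", "detectable",
]


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


@dataclass
class HiResDiveRecord:
    """Regularly sampled time-depth trace for a single dive.

    Depth is metres, positive downward.  Samples are spaced ``interval_s``
    seconds apart starting at ``start_utc``; the first and last samples are
    at the surface.
    """

    individual_id: str
    start_utc: pd.Timestamp
    interval_s: float
    depth: np.ndarray
    dive_id: str | None = None
    longitude: float = 0.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.interval_s <= 0:
            raise ValueError("sample interval must be positive")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative (positive down)")

    @property
    def n_samples(self) -> int:
        return len(self.depth)

    @property
    def times_s(self) -> np.ndarray:
        """Sample times as seconds from the dive start."""
        return np.arange(self.n_samples) * self.interval_s

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) * self.interval_s


@dataclass
class AbstractedDiveProfile:
    """Broken-stick summary of one dive: four at-depth inflection points.

    The two surface points are implicit at (0 s, 0 m) and
    (``duration_s``, 0 m).  ``inflection_times`` are seconds from dive
    start, strictly increasing and inside (0, duration).
    """

    dive_id: str
    individual_id: str
    start_utc: pd.Timestamp
    duration_s: float
    inflection_depths: np.ndarray
    inflection_times: np.ndarray
    longitude: float = 0.0
    latitude: float | None = None

    def __post_init__(self) -> None:
        self.inflection_depths = np.asarray(self.inflection_depths, dtype=float)
        self.inflection_times = np.asarray(self.inflection_times, dtype=float)

    def validate(self) -> None:
        t, d = self.inflection_times, self.inflection_depths
        if self.duration_s <= 0:
            raise ValueError(f"dive {self.dive_id}: non-positive duration")
        if len(t) != 4 or len(d) != 4:
            raise ValueError(f"dive {self.dive_id}: expected 4 inflection points")
        if not (np.all(np.diff(t) > 0) and t[0] > 0 and t[-1] < self.duration_s):
            raise ValueError(f"dive {self.dive_id}: inflection times not strictly "
                             "increasing inside (0, duration)")
        if np.any(d < 0):
            raise ValueError(f"dive {self.dive_id}: negative depth")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"dive {self.dive_id}: longitude out of range")

    @property
    def knot_times(self) -> np.ndarray:
        """All six knot times including the implicit surface points."""
        return np.concatenate(([0.0], self.inflection_times, [self.duration_s]))

    @property
    def knot_depths(self) -> np.ndarray:
        return np.concatenate(([0.0], self.inflection_depths, [0.0]))


def _provenance_line(meta: dict | None) -> str | None:
    if not meta:
        return None
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# driftdive {parts}"


def _write_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        line = _provenance_line(meta)
        if line:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# abstracted dive tables


def profiles_to_frame(profiles: Iterable[AbstractedDiveProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "individual_id": p.individual_id,
            "dive_id": p.dive_id,
            "start_utc": pd.Timestamp(p.start_utc).isoformat(),
            "duration_s": p.duration_s,
            "d1_m": p.inflection_depths[0], "d2_m": p.inflection_depths[1],
            "d3_m": p.inflection_depths[2], "d4_m": p.inflection_depths[3],
            "t1": p.inflection_times[0], "t2": p.inflection_times[1],
            "t3": p.inflection_times[2], "t4": p.inflection_times[3],
            "lon": p.longitude,
            "lat": p.latitude if p.latitude is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=ABSTRACTED_COLUMNS)


def write_abstracted(profiles: Sequence[AbstractedDiveProfile], path: str | Path,
                     meta: dict | None = None) -> None:
    """Write an abstracted dive table in the seconds dialect."""
    _write_csv(profiles_to_frame(profiles), path, meta)


def read_abstracted(path: str | Path, dialect: str = "seconds",
                    ) -> list[AbstractedDiveProfile]:
    """Read an abstracted dive table.

    ``dialect='percent'`` interprets t1..t4 as percentages of dive duration
    and converts them to seconds (t_i/100 * duration).  Rows violating the
    profile invariants (zero duration, non-monotone times, bad longitude)
    are skipped with a logged count.
    """
    if dialect not in ("seconds", "percent"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, comment="#")
    required = [c for c in ABSTRACTED_COLUMNS if c != "lat"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    profiles: list[AbstractedDiveProfile] = []
    n_skipped = 0
    for i, row in df.iterrows():
        try:
            start = pd.Timestamp(row["start_utc"])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"row {i}: unparseable timestamp "
                              f"{row['start_utc']!r}") from exc
        duration = float(row["duration_s"])
        times = np.array([row["t1"], row["t2"], row["t3"], row["t4"]], dtype=float)
        if dialect == "percent":
            times = times / 100.0 * duration
        lat = row.get("lat", np.nan)
        p = AbstractedDiveProfile(
            dive_id=str(row["dive_id"]),
            individual_id=str(row["individual_id"]),
            start_utc=start,
            duration_s=duration,
            inflection_depths=np.array(
                [row["d1_m"], row["d2_m"], row["d3_m"], row["d4_m"]], dtype=float),
            inflection_times=times,
            longitude=float(row["lon"]),
            latitude=None if pd.isna(lat) else float(lat),
        )
        try:
            p.validate()
        except ValueError as exc:
            logger.warning("skipping row %d: %s", i, exc)
            n_skipped += 1
            continue
        profiles.append(p)
    if n_skipped:
        logger.info("read_abstracted: skipped %d invalid row(s)", n_skipped)
    return profiles


# ---------------------------------------------------------------------------
# high-resolution records


def write_hires(records: Sequence[HiResDiveRecord], path: str | Path,
                meta: dict | None = None) -> None:
    """Write high-resolution records as (individual_id, timestamp_utc, depth_m).

    A ``dive_id`` column is included so records can be split back into
    dives on read.
    """
    frames = []
    for r in records:
        ts = pd.Timestamp(r.start_utc) + pd.to_timedelta(r.times_s, unit="s")
        frames.append(pd.DataFrame({
            "individual_id": r.individual_id,
            "dive_id": r.dive_id,
            "timestamp_utc": [t.isoformat() for t in ts],
            "depth_m": r.depth,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames else
          pd.DataFrame(columns=["individual_id", "dive_id", "timestamp_utc", "depth_m"]))
    _write_csv(df, path, meta)


def read_hires(path: str | Path) -> list[HiResDiveRecord]:
    df = pd.read_csv(path, comment="#")
    for col in ("individual_id", "dive_id", "timestamp_utc", "depth_m"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    records = []
    for dive_id, g in df.groupby("dive_id", sort=False):
        ts = pd.to_datetime(g["timestamp_utc"])
        steps = np.diff(ts.astype("int64")) / 1e9
        if len(steps) and not np.allclose(steps, steps[0]):
            raise FormatError(f"dive {dive_id}: irregular sampling")
        records.append(HiResDiveRecord(
            individual_id=str(g["individual_id"].iloc[0]),
            start_utc=ts.iloc[0],
            interval_s=float(steps[0]) if len(steps) else 1.0,
            depth=g["depth_m"].to_numpy(float),
            dive_id=str(dive_id),
        ))
    return records


# ---------------------------------------------------------------------------
# drift-rate series


def write_drift_series(series: pd.DataFrame, path: str | Path,
                       meta: dict | None = None) -> None:
    """Write a drift-rate series (one row per retained drift fragment).

    Expects columns individual_id, timestamp_utc, drift_rate_ms, dive_id,
    time-ordered.  Drift rates are rendered with six decimal places.
    """
    df = series.copy()
    if df.empty:
        df = pd.DataFrame(columns=DRIFT_SERIES_COLUMNS)
    else:
        df["timestamp_utc"] = [pd.Timestamp(t).isoformat()
                               for t in df["timestamp_utc"]]
    _write_csv(df[DRIFT_SERIES_COLUMNS], path, meta)


def read_drift_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DRIFT_SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"])
    df["dive_id"] = df["dive_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# ground-truth / visual label tables


def write_labels(labels: pd.DataFrame, path: str | Path,
                 meta: dict | None = None) -> None:
    cols = [c for c in LABEL_COLUMNS if c in labels.columns]
    _write_csv(labels[cols], path, meta)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "dive_id" not in df.columns or "dive_type" not in df.columns:
        raise FormatError("missing required column(s): dive_id, dive_type")
    df["dive_id"] = df["dive_id"].astype(str)
    if "detectable" in df.columns:
        df["detectable"] = df["detectable"].astype(bool)
    return df
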