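"""Preparation of abstracted dive profiles for drift filtering.

Each valid profile is split into the five fragments delimited by its six
inflection points.  For every fragment the vertical speed, duration,
percentage of dive duration, neighbouring fragment speeds and local
(solar) start time are derived.

Sign convention: depth is positive downward and vertical speed is
(depth_start - depth_end) / (t_end - t_start), so a sinking animal has a
negative vertical speed.  A passively sinking seal drifts at roughly
-0.05 to -0.6 m/s, which the filtering criteria use literally.

Fragments 1 and 5 (descent and ascent) and fragments whose two inflection
points share the same recorded depth (flat bottoms) are excluded from
drift candidacy, but their speeds still provide neighbour context.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .dive_io import AbstractedDiveProfile

logger = logging.getLogger("driftdive")

FRAGMENT_COLUMNS = [
    "dive_id", "individual_id", "fragment_index", "t_start_s", "t_end_s",
    "depth_start_m", "depth_end_m", "vspeed_ms", "duration_s", "pct_duration",
    "start_utc", "start_lt", "mid_lt", "prev_speed_ms", "next_speed_ms",
    "candidate",
]


def prepare_dives(profiles: Sequence[AbstractedDiveProfile],
                  ) -> list[AbstractedDiveProfile]:
    """Drop dives whose recorded duration is zero (or negative)."""
    kept = [p for p in profiles if p.duration_s > 0]
    n_removed = len(profiles) - len(kept)
    if n_removed:
        logger.info("prepare_dives: removed %d zero-duration dive(s)", n_removed)
    return kept


def local_time(utc, longitude: float) -> float:
    """Local solar mean time as fractional hours in [0, 24).

    lt = UTC + longitude / 15 h.  No civil time zones, no DST.
    """
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude} out of range [-180, 180]")
    ts = pd.Timestamp(utc)
    utc_hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 \
        + ts.microsecond / 3.6e9
    lt = (utc_hours + longitude / 15.0) % 24.0
    return lt if lt < 24.0 else 0.0       # guard float round-up at the wrap


def fragment_dive(profile: AbstractedDiveProfile) -> pd.DataFrame:
    """Split one abstracted profile into its five fragments."""
    return fragment_dives([profile])


def fragment_dives(profiles: Sequence[AbstractedDiveProfile]) -> pd.DataFrame:
    """Split each profile into five fragments with derived fields.

    Returns one row per fragment (5 per dive) with the columns in
    ``FRAGMENT_COLUMNS``.  Raises on non-monotone inflection times.
    """
    if len(profiles) == 0:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)

    rows = []
    for p in profiles:
        t = p.knot_times
        d = p.knot_depths
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"dive {p.dive_id}: non-monotone inflection times")
        dt = np.diff(t)
        speeds = (d[:-1] - d[1:]) / dt       # sinking -> negative
        start = pd.Timestamp(p.start_utc)
        for i in range(5):
            frag_start_utc = start + pd.Timedelta(seconds=float(t[i]))
            mid_utc = start + pd.Timedelta(seconds=float((t[i] + t[i + 1]) / 2))
            flat = d[i] == d[i + 1]
            rows.append({
                "dive_id": p.dive_id,
                "individual_id": p.individual_id,
                "fragment_index": i + 1,
                "t_start_s": float(t[i]),
                "t_end_s": float(t[i + 1]),
                "depth_start_m": float(d[i]),
                "depth_end_m": float(d[i + 1]),
                "vspeed_ms": float(speeds[i]),
                "duration_s": float(dt[i]),
                "pct_duration": float(dt[i] / p.duration_s * 100.0),
                "start_utc": frag_start_utc,
                "start_lt": local_time(frag_start_utc, p.longitude),
                "mid_lt": local_time(mid_utc, p.longitude),
                "prev_speed_ms": float(speeds[i - 1]) if i > 0 else np.nan,
                "next_speed_ms": float(speeds[i + 1]) if i < 4 else np.nan,
                "candidate": bool(i not in (0, 4) and not flat),
            })
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
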