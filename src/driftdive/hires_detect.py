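"""Statistical sliding-window drift detection on high-resolution records.

Used as the independent check on the abstracted-profile filtering: the
2 s depth trace is decimated to 40 s, vertical speeds are taken as
consecutive depth differences, and an 8 min window slides one sample at a
time over the parts of the dive deeper than 50 m.  Windows with a low
absolute mean vertical speed (< 1 m/s) and a low speed standard deviation
(< 0.05 m/s by default; noisier animals may need 0.075-0.1) are flagged
as drifting, and overlapping flagged windows are merged into maximal
drift segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dive_io import HiResDiveRecord


@dataclass
class HiResDetectorConfig:
    target_interval: float = 40.0        # s
    window: float = 480.0                # s (8 min)
    min_depth: float = 50.0              # m; windows must be wholly deeper
    max_abs_mean_speed: float = 1.0      # m/s
    max_speed_sd: float = 0.05           # m/s
    depth_gate: str = "all"              # "all" or "mean" samples below min_depth

    def __post_init__(self) -> None:
        if self.target_interval <= 0 or self.window <= 0:
            raise ValueError("intervals must be positive")
        if self.window % self.target_interval != 0:
            raise ValueError("window must be a multiple of target_interval")
        if min(self.max_abs_mean_speed, self.max_speed_sd, self.min_depth) <= 0:
            raise ValueError("thresholds must be positive")


def downsample(record: HiResDiveRecord, target_interval: float,
               ) -> HiResDiveRecord:
    """Decimate to ``target_interval`` by keeping every k-th sample."""
    ratio = target_interval / record.interval_s
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"target interval {target_interval} s is not an integer multiple "
            f"of the native {record.interval_s} s")
    k = int(round(ratio))
    return HiResDiveRecord(
        individual_id=record.individual_id,
        start_utc=record.start_utc,
        interval_s=target_interval,
        depth=record.depth[::k].copy(),
        dive_id=record.dive_id,
        longitude=record.longitude,
    )


def detect_drift_hires(record: HiResDiveRecord,
                       config: HiResDetectorConfig | None = None,
                       ) -> pd.DataFrame:
    """Detect drift segments in one dive.

    Returns a frame with one row per merged segment: dive_id, start_s,
    end_s (seconds from dive start), mean_vspeed_ms, n_windows.  An empty
    frame is returned (with a warning) when the dive is shorter than one
    window.
    """
    config = config or HiResDetectorConfig()
    rec = record
    if rec.interval_s != config.target_interval:
        rec = downsample(rec, config.target_interval)
    dt = rec.interval_s
    depth = rec.depth
    m = int(round(config.window / dt))       # speeds per window
    cols = ["dive_id", "start_s", "end_s", "mean_vspeed_ms", "n_windows"]
    if len(depth) < m + 1:
        import warnings
        warnings.warn(f"dive {rec.dive_id}: shorter than one window")
        return pd.DataFrame(columns=cols)

    # sinking -> negative, same convention as fragment speeds
    v = (depth[:-1] - depth[1:]) / dt
    win_v = np.lib.stride_tricks.sliding_window_view(v, m)
    win_d = np.lib.stride_tricks.sliding_window_view(depth, m + 1)
    mean_v = win_v.mean(axis=1)
    sd_v = win_v.std(axis=1, ddof=1)
    if config.depth_gate == "mean":
        deep = win_d.mean(axis=1) > config.min_depth
    else:
        deep = win_d.min(axis=1) > config.min_depth
    flagged = deep & (np.abs(mean_v) < config.max_abs_mean_speed) \
        & (sd_v < config.max_speed_sd)

    rows = []
    idx = np.flatnonzero(flagged)
    if len(idx):
        # merge windows that overlap or touch (starts within m samples)
        breaks = np.flatnonzero(np.diff(idx) > m)
        groups = np.split(idx, breaks + 1)
        for g in groups:
            i0, i1 = int(g[0]), int(g[-1])
            start_s = i0 * dt
            end_s = (i1 + m) * dt
            seg_v = v[i0:i1 + m]
            rows.append({
                "dive_id": rec.dive_id,
                "start_s": start_s,
                "end_s": end_s,
                "mean_vspeed_ms": float(seg_v.mean()),
                "n_windows": len(g),
            })
    return pd.DataFrame(rows, columns=cols)


def detect_deployment(records, config: HiResDetectorConfig | None = None,
                      ) -> pd.DataFrame:
    """Run the detector over every dive of a deployment."""
    import warnings
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in records:
            seg = detect_drift_hires(r, config)
            if not seg.empty:
                frames.append(seg)
    if not frames:
        return pd.DataFrame(
            columns=["dive_id", "start_s", "end_s", "mean_vspeed_ms", "n_windows"])
    return pd.concat(frames, ignore_index=True)
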