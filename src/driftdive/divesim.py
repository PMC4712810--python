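"""Synthetic dive-record simulator with planted drift phases.

Generates multi-month high-resolution (2 s) time-depth records for a
virtual elephant-seal deployment, containing:

* drift dives whose passive-drift rate follows a known buoyancy
  trajectory (logistic recovery from strongly negative towards
  near-neutral buoyancy) plus per-dive Gaussian noise;
* V-shaped and U-shaped (flat-bottom) dives as benign confounders;
* D-type dives whose oscillating bottom phase descends slowly inside the
  drift-speed band — the deliberate confounder that the abstracted
  filtering method is known to misclassify;
* a diel pattern concentrating drift dives in the early morning.

Every dive carries a ground-truth label.  ``detectable`` marks drift
dives whose planted drift phase satisfies all seven selection criteria
with a small safety margin, so that abstraction (0.5 m sensor
quantization, sample-grid snapping) cannot push them across a criterion
boundary; drift dives inside the margin band keep their label but are
not flagged detectable.

All simulator distributions are artifact choices (no generative model is
implied by the biology); geometry is chosen so that detectable drift
dives satisfy the criteria with margin, and active swimming phases carry
a stroke-like depth oscillation so that high-resolution detection sees
realistic vertical-speed variance outside drift phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dive_io import HiResDiveRecord
from .fragmentation import local_time


class SimConfigError(ValueError):
    pass


@dataclass
class BuoyancyTrajectory:
    """Logistic drift-rate trajectory v(t) in m/s over trip days.

    v(t) = v0 + (v1 - v0) / (1 + exp(-(t - t_mid)/scale)); monotone
    non-decreasing for v0 <= v1.  Defaults emulate a seal that leaves
    strongly negatively buoyant (-0.35 m/s) and approaches neutral
    buoyancy (-0.02 m/s) around day 75.
    """

    v0: float = -0.35
    v1: float = -0.02
    t_mid: float = 75.0
    scale: float = 15.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise SimConfigError("trajectory scale must be positive")

    def value(self, t) -> np.ndarray | float:
        from scipy.special import expit
        t = np.asarray(t, dtype=float)
        out = self.v0 + (self.v1 - self.v0) * expit((t - self.t_mid) / self.scale)
        return float(out) if out.ndim == 0 else out


def trajectory_value(trajectory: BuoyancyTrajectory, t) -> float:
    """Drift rate (m/s) of the buoyancy trajectory at trip day ``t``."""
    return trajectory.value(t)


DEFAULT_TYPE_MIX = {"drift": 0.04, "V": 0.46, "U": 0.40, "D": 0.10}


@dataclass
class SimConfig:
    n_days: int = 100
    dives_per_day: int = 40
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    drift_noise_sd: float = 0.03          # m/s, per-dive
    sample_interval: float = 2.0          # s
    depth_quantization: float = 0.5       # m, sensor resolution
    diel_peak_window: tuple = (2.0, 7.0)  # local hours with elevated drift prob
    diel_peak_mass: float = 0.6           # probability mass inside the window
    longitude: float = -36.5              # deg E (South Atlantic)
    longitude_track: object = None        # optional callable day -> lon
    individual_id: str = "sim01"
    start_date: str = "2009-02-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("type_mix proportions must sum to 1")
        unknown = set(self.type_mix) - {"drift", "V", "U", "D"}
        if unknown:
            raise SimConfigError(f"unknown dive type(s) in mix: {unknown}")
        if self.sample_interval <= 0:
            raise SimConfigError("sample_interval must be positive")
        if self.dives_per_day < 1:
            raise SimConfigError("dives_per_day must be >= 1")
        if self.n_days < 1:
            raise SimConfigError("n_days must be >= 1")

    def lon_at(self, day: float) -> float:
        if self.longitude_track is not None:
            return float(self.longitude_track(day))
        return self.longitude


# geometry constants (artifact choices; see docs/methods.md)
DESCENT_SPEED = 1.4          # m/s downward on active descents
ASCENT_STAGE_SPEEDS = (0.8, 1.1, 1.4)   # three-stage ascent after a drift
DRIFT_DURATION_RANGE = (540.0, 840.0)   # s
DRIFT_START_DEPTH_RANGE = (120.0, 430.0)  # m
MAX_DRIFT_END_DEPTH = 525.0  # keeps detectable drifts inside the 550 m bound
ACTIVE_OSC_AMPLITUDE = (2.5, 4.0)       # m, stroke-like wiggle on active phases
ACTIVE_OSC_PERIOD = (55.0, 75.0)        # s
D_ENVELOPE_RATE = (-0.55, -0.06)        # m/s, inside the drift-speed band

# safety margins for the `detectable` flag (absorb quantization + grid snap)
MARGIN_SPEED = 0.02      # m/s on the [-0.6, -0.05] band
MARGIN_DEPTH = 5.0       # m on the [100, 550] range
MARGIN_DURATION = 60.0   # s on the 480 s minimum
MARGIN_PCT = 2.0         # percentage points on the 40% minimum
MARGIN_LT_H = 10.0 / 60.0  # h on the 13:30-19:30 exclusion window


def _segments_drift(rng: np.random.Generator, v: float):
    """Corner points of a drift dive: descent, drift, 3-stage ascent.

    Returns (times, depths, active_flags) where corners delimit five
    linear segments (exactly four interior breakpoints, so broken-stick
    abstraction recovers them exactly).
    """
    t_d = rng.uniform(*DRIFT_DURATION_RANGE)
    sink = max(0.0, -v) * t_d
    d0_hi = min(DRIFT_START_DEPTH_RANGE[1], MAX_DRIFT_END_DEPTH - sink)
    d0 = rng.uniform(DRIFT_START_DEPTH_RANGE[0], max(DRIFT_START_DEPTH_RANGE[0] + 10.0, d0_hi))
    if v > 0:                                  # rare rising drift (noise): stay submerged
        t_d = min(t_d, max(60.0, (d0 - 50.0) / v))
    d1 = d0 - v * t_d
    t = [0.0, d0 / DESCENT_SPEED]
    d = [0.0, d0]
    t.append(t[-1] + t_d)
    d.append(d1)
    remaining = d1
    for s in ASCENT_STAGE_SPEEDS:
        step = d1 / 3.0
        remaining -= step
        t.append(t[-1] + step / s)
        d.append(max(0.0, remaining))
    d[-1] = 0.0
    active = [True, False, True, True, True]
    return np.array(t), np.array(d), active, (t[1], t[1] + t_d, t_d, d0, d1)


def _segments_v(rng: np.random.Generator):
    depth = rng.uniform(100.0, 600.0)
    sd = rng.uniform(1.2, 1.8)
    sa = rng.uniform(1.0, 1.6)
    t = np.array([0.0, depth / sd, depth / sd + depth / sa])
    d = np.array([0.0, depth, 0.0])
    return t, d, [True, True]


def _segments_u(rng: np.random.Generator):
    depth = rng.uniform(150.0, 500.0)
    t_b = rng.uniform(300.0, 900.0)
    slope = 0.0 if rng.random() < 0.5 else rng.uniform(-0.03, 0.03)
    d_end = max(50.0, depth + (-slope) * t_b)   # slope is a vertical speed
    sd = rng.uniform(1.2, 1.8)
    sa = rng.uniform(1.0, 1.6)
    t = np.array([0.0, depth / sd, depth / sd + t_b,
                  depth / sd + t_b + d_end / sa])
    d = np.array([0.0, depth, d_end, 0.0])
    return t, d, [True, True, True]


def _segments_d(rng: np.random.Generator):
    """D-type dive: bottom depth oscillations on a sinking envelope.

    Modelled as two slow glide-down limbs separated by a quick upward
    recovery stroke — the animal drifts down parts of the oscillation.
    The limb rates sit inside the drift-speed band, so after broken-stick
    abstraction (which has exactly enough points for the four bottom
    corners) the first limb can imitate a genuine drift fragment: the
    documented false-positive mode of the filtering method.
    """
    d0 = rng.uniform(150.0, 380.0)
    r1 = rng.uniform(*D_ENVELOPE_RATE)          # negative: gliding down
    g1 = rng.uniform(280.0, 680.0)
    rec_dur = rng.uniform(40.0, 80.0)
    rec_speed = rng.uniform(1.0, 1.5)           # upward recovery stroke
    r2 = rng.uniform(*D_ENVELOPE_RATE)
    g2 = rng.uniform(120.0, 360.0)
    sd = rng.uniform(1.2, 1.8)
    sa = rng.uniform(1.2, 1.8)
    d1 = d0 - r1 * g1
    d2 = max(60.0, d1 - rec_speed * rec_dur)
    d3 = d2 - r2 * g2
    t = [0.0, d0 / sd]
    d = [0.0, d0]
    for dur, dep in [(g1, d1), (rec_dur, d2), (g2, d3), (d3 / sa, 0.0)]:
        t.append(t[-1] + dur)
        d.append(dep)
    # glide limbs carry the active stroke wiggle so only the abstracted
    # profile, not the high-resolution trace, looks like passive drift
    return np.array(t), np.array(d), [True, True, True, True, True]


def _sample_dive(times, depths, active, dt, rng):
    """Sample the piecewise-linear dive on the regular grid and add a
    tapered stroke-like sinusoidal wiggle to the active segments."""
    total = times[-1]
    n = int(math.ceil(total / dt)) + 1
    tg = np.arange(n) * dt
    depth = np.interp(np.minimum(tg, total), times, depths)
    for i in range(len(times) - 1):
        if not active[i]:
            continue
        t0, t1 = times[i], times[i + 1]
        if t1 - t0 < 4 * dt:
            continue
        sel = (tg > t0) & (tg < t1)
        if not np.any(sel):
            continue
        amp = rng.uniform(*ACTIVE_OSC_AMPLITUDE)
        per = rng.uniform(*ACTIVE_OSC_PERIOD)
        # 30 s ramp at the segment edges keeps the corner depths exact
        # without quieting the stroke noise over the segment interior
        ramp = np.minimum(1.0, np.minimum((tg[sel] - t0) / 30.0,
                                          (t1 - tg[sel]) / 30.0))
        phase = rng.uniform(0, 2 * np.pi)
        depth[sel] += amp * np.sin(2 * np.pi * (tg[sel] - t0) / per + phase) \
            * ramp
    return np.maximum(depth, 0.0)


def _drift_detectable(v, t_d, d0, d1, total, lt_frag) -> bool:
    """Does the planted drift phase satisfy all seven criteria with margin?"""
    if not (-0.6 + MARGIN_SPEED <= v <= -0.05 - MARGIN_SPEED):
        return False
    lo, hi = 100.0 + MARGIN_DEPTH, 550.0 - MARGIN_DEPTH
    if not (lo <= d0 <= hi and lo <= d1 <= hi):
        return False
    if t_d <= 480.0 + MARGIN_DURATION:
        return False
    if t_d / total * 100.0 < 40.0 + MARGIN_PCT:
        return False
    # descent at -1.4 and first ascent stage at +0.8 satisfy criteria 7 and 5
    if 13.5 - MARGIN_LT_H <= lt_frag < 19.5 + MARGIN_LT_H:
        return False
    return True


def simulate_deployment(config: SimConfig,
                        trajectory: BuoyancyTrajectory | None = None,
                        ) -> tuple[list[HiResDiveRecord], pd.DataFrame]:
    """Simulate a deployment: one high-resolution record per dive + labels.

    Returns ``(records, labels)`` where labels has one row per dive with
    columns dive_id, individual_id, dive_type, true_drift_rate,
    drift_start_s, drift_end_s, detectable, start_utc, longitude,
    duration_s, trip_day.  Identical seeds give identical output.
    """
    trajectory = trajectory or BuoyancyTrajectory()
    rng = np.random.default_rng(config.seed)
    base = pd.Timestamp(config.start_date)
    types = sorted(config.type_mix)              # deterministic order
    probs = np.array([config.type_mix[k] for k in types])

    # draw per-dive (day, start hour UTC, type)
    plan = []
    for day in range(config.n_days):
        lon = config.lon_at(day)
        for _ in range(config.dives_per_day):
            dtype = types[rng.choice(len(types), p=probs)]
            if dtype == "drift" and rng.random() < config.diel_peak_mass:
                lt = rng.uniform(*config.diel_peak_window)
            else:
                lt = rng.uniform(0.0, 24.0)
            utc_h = (lt - lon / 15.0) % 24.0
            plan.append((day * 24.0 + utc_h, day, dtype, lon))
    plan.sort(key=lambda x: x[0])

    records: list[HiResDiveRecord] = []
    rows = []
    prev_end_h = -np.inf
    dt = config.sample_interval
    q = config.depth_quantization
    for i, (start_h, day, dtype, lon) in enumerate(plan):
        gap_s = rng.exponential(120.0)
        start_h = max(start_h, prev_end_h + gap_s / 3600.0)
        start_utc = base + pd.Timedelta(hours=start_h)
        dive_id = f"{config.individual_id}_{i:05d}"

        true_rate = np.nan
        drift_start = drift_end = np.nan
        detectable = False
        if dtype == "drift":
            v = float(trajectory.value(start_h / 24.0))
            if config.drift_noise_sd > 0:
                v += rng.normal(0.0, config.drift_noise_sd)
            times, depths, active, (ta, tb, t_d, d0, d1) = _segments_drift(rng, v)
            true_rate = v
            drift_start, drift_end = ta, tb
            lt_frag = local_time(start_utc + pd.Timedelta(seconds=ta), lon)
            detectable = _drift_detectable(v, t_d, d0, d1, times[-1], lt_frag)
        elif dtype == "V":
            times, depths, active = _segments_v(rng)
        elif dtype == "U":
            times, depths, active = _segments_u(rng)
        else:
            times, depths, active = _segments_d(rng)

        depth = _sample_dive(times, depths, active, dt, rng)
        if q > 0:
            depth = np.round(depth / q) * q
        depth[0] = depth[-1] = 0.0
        records.append(HiResDiveRecord(
            individual_id=config.individual_id, start_utc=start_utc,
            interval_s=dt, depth=depth, dive_id=dive_id, longitude=lon))
        rows.append({
            "dive_id": dive_id, "individual_id": config.individual_id,
            "dive_type": dtype, "true_drift_rate": true_rate,
            "drift_start_s": drift_start, "drift_end_s": drift_end,
            "detectable": detectable, "start_utc": start_utc,
            "longitude": lon, "duration_s": float(times[-1]),
            "trip_day": start_h / 24.0,
        })
        prev_end_h = start_h + times[-1] / 3600.0

    labels = pd.DataFrame(rows)
    return records, labels
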