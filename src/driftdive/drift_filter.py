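"""Step-wise selection of drift fragments from abstracted dive profiles.

Seven knowledge-based criteria are applied conjunctively to the candidate
fragments (indices 2-4 that survived preparation).  A fragment is a drift
fragment iff it passes all of them; its vertical speed is then the drift
rate, a direct proxy for the animal's buoyancy and hence body composition.

Criteria (defaults for negatively buoyant southern elephant seals):

1. speed        -0.6 <= v <= -0.05 m/s (passive sinking band, inclusive)
2. depth        fragment starts and ends between 100 and 550 m (lungs
                collapsed below ~100 m, so residual air no longer affects
                buoyancy; drifts terminate shallower than 550 m)
3. length       duration strictly greater than 8 min (statistics-based
                minimum, see the min_length module)
4. pct          fragment covers at least 40% of the dive duration
5. next_ascent  following fragment ascends at >= 0.2 m/s (the seal must
                surface to breathe after drifting)
6. time_of_day  fragments starting within 13:30-19:30 local (solar) time
                are discarded (drift dives are a night/morning behaviour)
7. prev_descent following an active descent: preceding fragment at
                <= -0.6 m/s

Boundary handling: all numeric bounds are inclusive except criterion 3
(strict ">", "longer than 8 min") and the local-time window, which is
half-open [13:30, 19:30).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FilterConfigError(ValueError):
    pass


@dataclass
class FilterConfig:
    speed_min: float = -0.6          # m/s
    speed_max: float = -0.05         # m/s
    depth_min: float = 100.0         # m
    depth_max: float = 550.0         # m
    min_duration: float = 480.0      # s, strict
    min_pct: float = 40.0            # % of dive duration
    next_speed_min: float = 0.2      # m/s
    prev_speed_max: float = -0.6     # m/s
    lt_excl_start: float = 13.5      # local hours
    lt_excl_end: float = 19.5        # local hours, half-open
    lt_anchor: str = "start"         # "start" or "midpoint" of the fragment
    allow_positive: bool = False     # widen speed_max for buoyant animals

    def __post_init__(self) -> None:
        if not self.allow_positive and self.speed_max > 0:
            raise FilterConfigError(
                "speed_max > 0 requires allow_positive=True")
        if self.speed_min >= self.speed_max:
            raise FilterConfigError("speed_min must be < speed_max")
        if self.depth_min >= self.depth_max:
            raise FilterConfigError("depth_min must be < depth_max")
        if self.min_duration <= 0:
            raise FilterConfigError("min_duration must be positive")
        if not 0 < self.min_pct <= 100:
            raise FilterConfigError("min_pct must be in (0, 100]")
        if self.lt_anchor not in ("start", "midpoint"):
            raise FilterConfigError("lt_anchor must be 'start' or 'midpoint'")


def criterion_1_speed(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    v = f["vspeed_ms"]
    return (v >= c.speed_min) & (v <= c.speed_max)


def criterion_2_depth(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    return ((f["depth_start_m"] >= c.depth_min)
            & (f["depth_start_m"] <= c.depth_max)
            & (f["depth_end_m"] >= c.depth_min)
            & (f["depth_end_m"] <= c.depth_max))


def criterion_3_length(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    return f["duration_s"] > c.min_duration


def criterion_4_pct(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    return f["pct_duration"] >= c.min_pct


def criterion_5_next(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    # a missing neighbour (profile edge) fails: no evidence of active ascent
    return (f["next_speed_ms"] >= c.next_speed_min).fillna(False)


def criterion_6_time(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    lt = f["start_lt"] if c.lt_anchor == "start" else f["mid_lt"]
    lo, hi = c.lt_excl_start, c.lt_excl_end
    if lo <= hi:
        inside = (lt >= lo) & (lt < hi)
    else:                                   # window wraps midnight
        inside = (lt >= lo) | (lt < hi)
    return ~inside


def criterion_7_prev(f: pd.DataFrame, c: FilterConfig) -> pd.Series:
    return (f["prev_speed_ms"] <= c.prev_speed_max).fillna(False)


CRITERIA = {
    "speed": criterion_1_speed,
    "depth": criterion_2_depth,
    "length": criterion_3_length,
    "pct": criterion_4_pct,
    "next_ascent": criterion_5_next,
    "time_of_day": criterion_6_time,
    "prev_descent": criterion_7_prev,
}

DEFAULT_ORDER = tuple(CRITERIA)


@dataclass
class FilterReport:
    """Retention bookkeeping for one step-wise filtering run.

    ``single_criterion`` gives, per criterion applied alone, the retained
    count and the retained percentage with two denominators: the candidate
    fragments and all fragments of the prepared dives.
    """

    n_all_fragments: int
    n_candidates: int
    single_criterion: dict
    stepwise: list            # [(criterion, remaining count), ...] in order
    final_ids: list
    n_dives: int
    n_drift_dives: int
    pct_dives_drift: float

    def to_dict(self) -> dict:
        return asdict(self)


def apply_filters(fragments: pd.DataFrame, config: FilterConfig | None = None,
                  order: Sequence[str] = DEFAULT_ORDER,
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the seven criteria step-wise to the candidate fragments.

    Returns the retained drift fragments and a report with single-criterion
    and cumulative retention.  Criteria are conjunctive, so the final set
    is identical for every permutation of ``order``.
    """
    config = config or FilterConfig()
    unknown = [name for name in order if name not in CRITERIA]
    if unknown:
        raise FilterConfigError(f"unknown criterion name(s): {unknown}")

    cand = fragments[fragments["candidate"].astype(bool)]
    masks = {name: CRITERIA[name](cand, config) for name in order}

    single = {}
    for name in order:
        kept = int(masks[name].sum())
        single[name] = {
            "retained": kept,
            "pct_of_candidates": 100.0 * kept / len(cand) if len(cand) else np.nan,
            "pct_of_all": (100.0 * kept / len(fragments)
                           if len(fragments) else np.nan),
        }

    stepwise = []
    current = pd.Series(True, index=cand.index)
    for name in order:
        current &= masks[name]
        stepwise.append((name, int(current.sum())))

    drift = cand[current].sort_values(["individual_id", "start_utc"])
    n_dives = fragments["dive_id"].nunique()
    n_drift_dives = drift["dive_id"].nunique()
    report = FilterReport(
        n_all_fragments=len(fragments),
        n_candidates=len(cand),
        single_criterion=single,
        stepwise=stepwise,
        final_ids=list(drift["dive_id"].astype(str) + "/"
                       + drift["fragment_index"].astype(str)),
        n_dives=n_dives,
        n_drift_dives=n_drift_dives,
        pct_dives_drift=100.0 * n_drift_dives / n_dives if n_dives else np.nan,
    )
    return drift, report


def extract_drift_series(drift_fragments: pd.DataFrame) -> pd.DataFrame:
    """Time-ordered drift-rate series, one row per retained drift fragment.

    Columns: individual_id, timestamp_utc (absolute fragment start),
    drift_rate_ms, dive_id.
    """
    if drift_fragments.empty:
        return pd.DataFrame(
            columns=["individual_id", "timestamp_utc", "drift_rate_ms", "dive_id"])
    out = pd.DataFrame({
        "individual_id": drift_fragments["individual_id"].values,
        "timestamp_utc": pd.to_datetime(drift_fragments["start_utc"].values),
        "drift_rate_ms": drift_fragments["vspeed_ms"].values,
        "dive_id": drift_fragments["dive_id"].astype(str).values,
    })
    return out.sort_values(["individual_id", "timestamp_utc"]).reset_index(drop=True)
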