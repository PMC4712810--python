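"""Broken-stick abstraction of high-resolution dives.

Satellite-relay data loggers compress each recorded dive on board to four
at-depth inflection points plus the two surface endpoints before
transmission.  This module re-implements that abstraction so the
high-resolution and abstracted representations of the same dive can be
connected: points are added iteratively, each time choosing the sample
whose depth deviates most (vertically) from the current polyline.

Tie-breaks go to the earliest sample, and residuals are vertical depth
differences, not perpendicular distances — the standard iterative
end-point fit for time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dive_io import AbstractedDiveProfile, HiResDiveRecord

DEFAULT_SURFACE_THRESHOLD_M = 2.0


class AbstractionError(ValueError):
    """Dive unsuitable for broken-stick abstraction."""


@dataclass
class BrokenStickResult:
    profile: AbstractedDiveProfile
    max_residual: float          # largest remaining vertical deviation (m)
    selection_order: list[int]   # sample indices, in the order chosen


def abstract_dive(dive: HiResDiveRecord, n_points: int = 4,
                  surface_threshold: float = DEFAULT_SURFACE_THRESHOLD_M,
                  ) -> BrokenStickResult:
    """Reduce a high-resolution dive to ``n_points`` at-depth inflection points.

    Starting from the two surface endpoints, repeatedly add the sample with
    the largest absolute vertical residual against linear interpolation
    through the currently selected points.  Any dive that is piecewise
    linear with at most ``n_points`` interior breakpoints is reproduced
    exactly (max_residual 0).
    """
    t = dive.times_s
    d = dive.depth
    n = len(d)
    if n < n_points + 2:
        raise AbstractionError(
            f"dive has {n} samples; need at least {n_points + 2}")
    if d[0] > surface_threshold or d[-1] > surface_threshold:
        raise AbstractionError(
            f"dive does not start and end at the surface "
            f"(threshold {surface_threshold} m)")

    selected = [0, n - 1]
    order: list[int] = []
    for _ in range(n_points):
        idx = np.sort(selected)
        resid = np.abs(d - np.interp(t, t[idx], d[idx]))
        resid[idx] = -1.0                     # never re-select a chosen sample
        pick = int(np.argmax(resid))          # argmax ties -> earliest sample
        order.append(pick)
        selected.append(pick)

    idx = np.sort(selected)
    max_residual = float(np.max(np.abs(d - np.interp(t, t[idx], d[idx]))))

    interior = np.sort(order)
    profile = AbstractedDiveProfile(
        dive_id=dive.dive_id if dive.dive_id is not None else "",
        individual_id=dive.individual_id,
        start_utc=dive.start_utc,
        duration_s=float(t[-1]),
        inflection_depths=d[interior].copy(),
        inflection_times=t[interior].astype(float),
        longitude=dive.longitude,
    )
    return BrokenStickResult(profile=profile, max_residual=max_residual,
                             selection_order=order)


def abstract_deployment(records, n_points: int = 4,
                        surface_threshold: float = DEFAULT_SURFACE_THRESHOLD_M,
                        ) -> list[BrokenStickResult]:
    """Abstract every dive of a deployment."""
    return [abstract_dive(r, n_points=n_points,
                          surface_threshold=surface_threshold) for r in records]


def reconstruct(profile: AbstractedDiveProfile, at_times) -> np.ndarray:
    """Evaluate the abstracted polyline (six knots) at times within the dive.

    ``at_times`` are seconds from the dive start and must lie in
    [0, duration]; the surface endpoints pin the depth to 0 m there.
    """
    at_times = np.atleast_1d(np.asarray(at_times, dtype=float))
    if np.any(at_times < 0) or np.any(at_times > profile.duration_s):
        raise ValueError("requested time outside the dive")
    return np.interp(at_times, profile.knot_times, profile.knot_depths)
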