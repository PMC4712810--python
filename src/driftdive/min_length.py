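"""Statistics-based derivation of the minimum drift-fragment length.

The minimum-length criterion (fragments must exceed 8 min) is derived by
subsampling candidate fragments at increasing length thresholds, fitting
a cross-validated cubic smoothing spline to each subsample's vertical
speed vs time, and locating the threshold with the most substantial
improvement in goodness of fit (R^2).  Short fragments carry mostly
abstraction noise, so the fit improves sharply once they are excluded.

The published procedure reads the inflection off a boxplot by eye; the
algorithmic detector here (first local maximum of the first differences
of the median R^2 curve) is one deterministic operationalisation, so the
full curve is always returned for inspection alongside the
recommendation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .drift_filter import CRITERIA, FilterConfig

logger = logging.getLogger("driftdive")

DEFAULT_THRESHOLDS = tuple(range(1, 16))   # minutes


class UndefinedVarianceError(ValueError):
    pass


class AnalysisError(ValueError):
    pass


@dataclass
class R2Curve:
    thresholds: np.ndarray                  # minutes, strictly increasing
    r2_by_individual: pd.DataFrame          # individuals x thresholds
    n_fragments: pd.DataFrame               # counts per cell

    @property
    def median(self) -> pd.Series:
        """Median R^2 across individuals per threshold."""
        return self.r2_by_individual.median(axis=0, skipna=True)


def r_squared(observed, fitted) -> float:
    """R^2 = 1 - (residual sum of squares / total sum of squares)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed and fitted must be equal-length, size >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise UndefinedVarianceError("observed values are all equal")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss


def _fit_speed_spline(times_days: np.ndarray, speeds: np.ndarray) -> np.ndarray:
    """GCV cubic smoothing spline of speed vs time, evaluated at the data.

    Duplicate abscissae are averaged before fitting (the spline needs
    strictly increasing x); fitted values are then mapped back to every
    original point.
    """
    order = np.argsort(times_days, kind="stable")
    x = times_days[order]
    y = speeds[order]
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < 5:
        raise AnalysisError("need at least 5 distinct time points")
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    spl = make_smoothing_spline(ux, uy)
    fitted_sorted = spl(x)
    out = np.empty_like(fitted_sorted)
    out[order] = fitted_sorted
    return out


def build_r2_curve(fragments: pd.DataFrame,
                   thresholds=DEFAULT_THRESHOLDS,
                   min_n: int = 10) -> R2Curve:
    """R^2 of speed-vs-time smoothing splines per (individual, threshold).

    For each threshold x the subsample holds the candidate fragments
    longer than x minutes; cells with fewer than ``min_n`` fragments (or
    a degenerate fit) are missing.  Raises if every cell at some
    threshold is missing.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    cand = fragments[fragments["candidate"].astype(bool)]
    individuals = sorted(cand["individual_id"].unique())
    if not individuals:
        raise AnalysisError("no candidate fragments")
    t0 = pd.to_datetime(cand["start_utc"]).min()
    r2 = pd.DataFrame(np.nan, index=individuals, columns=thresholds)
    counts = pd.DataFrame(0, index=individuals, columns=thresholds)
    for ind, g in cand.groupby("individual_id"):
        tdays = ((pd.to_datetime(g["start_utc"]) - t0)
                 / pd.Timedelta(days=1)).to_numpy(float)
        speeds = g["vspeed_ms"].to_numpy(float)
        durations_min = g["duration_s"].to_numpy(float) / 60.0
        for x in thresholds:
            sel = durations_min > x
            counts.loc[ind, x] = int(sel.sum())
            if sel.sum() < min_n:
                continue
            try:
                fitted = _fit_speed_spline(tdays[sel], speeds[sel])
                r2.loc[ind, x] = r_squared(speeds[sel], fitted)
            except (AnalysisError, UndefinedVarianceError) as exc:
                logger.debug("R2 cell (%s, %g min) missing: %s", ind, x, exc)
    dead = [float(x) for x in thresholds if r2[x].isna().all()]
    if dead:
        raise AnalysisError(
            f"no individual has enough fragments at threshold(s) {dead} min")
    return R2Curve(thresholds=thresholds, r2_by_individual=r2,
                   n_fragments=counts)


def find_inflection(curve: R2Curve, min_improvement: float = 0.05,
                    ) -> tuple[float | None, pd.DataFrame]:
    """Recommended minimum fragment length from the median R^2 curve.

    Takes first differences d(x) = R^2(x) - R^2(x_prev) of the median
    curve and returns the smallest threshold at the first local maximum
    of d exceeding ``min_improvement`` — the most substantial single-step
    improvement of fit.  Returns (None, diagnostics) with a warning when
    the curve is monotone-flat (no qualifying local maximum).
    """
    med = curve.median.dropna()
    if len(med) < 4:
        raise AnalysisError("need >= 4 thresholds with non-missing medians")
    x = med.index.to_numpy(float)
    delta = np.diff(med.to_numpy(float))
    diag = pd.DataFrame({"threshold_min": x,
                         "median_r2": med.to_numpy(float),
                         "delta_r2": np.concatenate(([np.nan], delta))})
    eps = 1e-9                                   # absorb float noise in ties
    last = len(delta) - 1
    for j in range(len(delta)):                  # delta[j] is the step into x[j+1]
        ge_left = j == 0 or delta[j] >= delta[j - 1] - eps
        ge_right = j == last or delta[j] >= delta[j + 1] - eps
        strict = (j > 0 and delta[j] > delta[j - 1] + eps) \
            or (j < last and delta[j] > delta[j + 1] + eps)
        if ge_left and ge_right and strict and delta[j] > min_improvement:
            return float(x[j + 1]), diag
    logger.warning("find_inflection: no substantial improvement found "
                   "(all steps flat or monotone)")
    return None, diag


def count_by_length(fragments: pd.DataFrame,
                    config: FilterConfig | None = None,
                    bin_min: float = 1.0) -> pd.Series:
    """Duration histogram of fragments surviving the other six criteria.

    Applies every criterion except the minimum-length one, bins the
    survivors' durations (1-min bins by default, labelled by the bin's
    lower edge in minutes).  The modal bin is a diagnostic for where a
    length cut-off keeps the most genuine drift fragments.
    """
    config = config or FilterConfig()
    cand = fragments[fragments["candidate"].astype(bool)]
    if cand.empty:
        return pd.Series(dtype=int, name="count")
    keep = pd.Series(True, index=cand.index)
    for name, fn in CRITERIA.items():
        if name == "length":
            continue
        keep &= fn(cand, config)
    surv = cand[keep]
    if surv.empty:
        return pd.Series(dtype=int, name="count")
    bins = np.floor(surv["duration_s"] / 60.0 / bin_min) * bin_min
    return bins.value_counts().sort_index().rename("count")
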