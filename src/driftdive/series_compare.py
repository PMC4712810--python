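"""Comparison of drift-rate time series against a reference.

Verifies that a filtered drift-rate series tracks the same buoyancy
signal as an independently obtained one (e.g. visually confirmed drift
rates for the same animal).  Because daily mean drift rates are strongly
autocorrelated, a raw Pearson correlation would be anticonservative;
instead both series are reduced to daily means, differenced to
stationarity by the order an automated ARIMA selection suggests, and the
observed correlation is referred to an empirical null of correlations
between pairs of series simulated from the two fitted ARIMA models.

Also provides the two-cell chi-square comparison of drift-dive counts
between migrations and per-dive verification against ground-truth or
visual labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import kpss


class ModelSelectionError(RuntimeError):
    pass


@dataclass
class ArimaSpec:
    p: int
    d: int
    q: int
    ar: tuple = ()
    ma: tuple = ()
    innovation_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be non-negative")
        if len(self.ar) != self.p or len(self.ma) != self.q:
            raise ValueError("coefficient lengths must match orders")
        if self.p and np.any(np.abs(np.roots([-c for c in self.ar[::-1]] + [1.0])) <= 1):
            raise ValueError("AR polynomial is not stationary")
        if self.q and np.any(np.abs(np.roots(list(self.ma[::-1]) + [1.0])) <= 1):
            raise ValueError("MA polynomial is not invertible")


@dataclass
class NullCorrelationResult:
    r_observed: float
    null_r: np.ndarray
    p_value: float
    n_overlap: int


@dataclass
class VerificationSummary:
    n_selected: int
    n_confirmed: int
    n_false_positive: int
    n_missed: int

    @property
    def confirmation_pct(self) -> float:
        return 100.0 * self.n_confirmed / self.n_selected if self.n_selected else np.nan

    def to_dict(self) -> dict:
        return {"n_selected": self.n_selected, "n_confirmed": self.n_confirmed,
                "n_false_positive": self.n_false_positive,
                "n_missed": self.n_missed,
                "confirmation_pct": self.confirmation_pct}


# ---------------------------------------------------------------------------
# daily reduction and differencing


def daily_mean(series: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean drift rate per calendar day (days without
    observations are absent, not zero-filled)."""
    if len(series) == 0:
        return pd.DataFrame(columns=["date", "drift_rate_ms"])
    df = series.copy()
    df["date"] = pd.to_datetime(df["timestamp_utc"]).dt.normalize()
    out = (df.groupby("date", as_index=False)["drift_rate_ms"].mean()
           .sort_values("date").reset_index(drop=True))
    return out


def fill_short_gaps(daily: pd.DataFrame, max_gap_days: int = 3,
                    ) -> list[np.ndarray]:
    """Contiguous daily arrays for ARIMA fitting.

    Gaps of at most ``max_gap_days`` missing days are linearly
    interpolated; longer gaps split the series.
    """
    if len(daily) == 0:
        return []
    s = daily.set_index("date")["drift_rate_ms"]
    full = s.reindex(pd.date_range(s.index.min(), s.index.max(), freq="D"))
    gap_id = full.notna().cumsum()
    runs = full.isna().groupby(gap_id).sum()
    split_after = runs[runs > max_gap_days].index
    boundaries = sorted(int(g) for g in split_after)
    interp = full.interpolate(limit=max_gap_days, limit_area="inside")
    pieces, start = [], 0
    obs_pos = np.flatnonzero(full.notna().to_numpy())
    for g in boundaries:
        end = obs_pos[g - 1] + 1
        pieces.append(interp.iloc[start:end])
        start = obs_pos[g] if g < len(obs_pos) else len(full)
    pieces.append(interp.iloc[start:])
    return [p.dropna().to_numpy(float) for p in pieces if p.notna().sum() > 0]


def difference_to_stationary(values, d: int) -> np.ndarray:
    """d-fold first differencing (length shrinks by d)."""
    values = np.asarray(values, dtype=float)
    if d < 0:
        raise ValueError("d must be non-negative")
    if len(values) < d + 2:
        raise ValueError(f"series of length {len(values)} too short for d={d}")
    return np.diff(values, n=d) if d else values.copy()


# ---------------------------------------------------------------------------
# automated ARIMA selection


def _kpss_d(values: np.ndarray, max_d: int = 2, alpha: float = 0.05) -> int:
    """Differencing order by repeated KPSS level-stationarity testing."""
    d = 0
    x = values
    while d < max_d:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pval, *_ = kpss(x, regression="c", nlags="auto")
        if pval >= alpha:
            break
        x = np.diff(x)
        d += 1
    return d


def select_arima(values, max_p: int = 5, max_q: int = 5, max_d: int = 2,
                 ) -> ArimaSpec:
    """Automated ARIMA order selection and fit on a daily series.

    d comes from repeated KPSS testing; (p, q) from a corrected-AIC grid
    search at that d; coefficients by maximum likelihood.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ModelSelectionError(
            f"need >= 20 daily values, got {len(values)}")
    d = _kpss_d(values, max_d=max_d)
    best = None
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = ARIMA(values, order=(p, d, q), trend=None,
                                ).fit(method_kwargs={"maxiter": 200})
                k = p + q + 1
                n_eff = len(values) - d
                aicc = fit.aic + 2 * k * (k + 1) / max(n_eff - k - 1, 1)
            except Exception:
                continue
            if best is None or aicc < best[0]:
                best = (aicc, p, q, fit)
    if best is None:
        raise ModelSelectionError("no ARIMA order converged")
    _, p, q, fit = best
    return ArimaSpec(p=p, d=d, q=q,
                     ar=tuple(np.atleast_1d(fit.arparams)) if p else (),
                     ma=tuple(np.atleast_1d(fit.maparams)) if q else (),
                     innovation_sd=float(np.sqrt(fit.params[-1])))


def simulate_arima(spec: ArimaSpec, n: int, rng: np.random.Generator,
                   burn: int = 200) -> np.ndarray:
    """Simulate one series of length n from the spec (integrated d times)."""
    e = rng.normal(0.0, spec.innovation_sd, size=n + burn)
    x = signal.lfilter(np.r_[1.0, spec.ma], np.r_[1.0, -np.asarray(spec.ar)], e)
    x = x[burn:]
    for _ in range(spec.d):
        x = np.cumsum(x)
    return x


# ---------------------------------------------------------------------------
# correlation and the simulated null


def correlate_pair(a, b) -> float:
    """Pearson product-moment correlation of two aligned series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must be aligned to equal length")
    if len(a) < 3:
        raise ValueError("need >= 3 overlapping days")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def align_daily(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Day-matched value pairs from two daily-mean frames."""
    merged = a.merge(b, on="date", suffixes=("_a", "_b"))
    return (merged["drift_rate_ms_a"].to_numpy(float),
            merged["drift_rate_ms_b"].to_numpy(float))


def _corr_rows(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (N, L) arrays."""
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    num = (xa * xb).sum(axis=1)
    den = np.sqrt((xa ** 2).sum(axis=1) * (xb ** 2).sum(axis=1))
    return num / den


def null_correlation(spec_a: ArimaSpec, spec_b: ArimaSpec, n_days: int,
                     r_observed: float, n_sim: int = 1000,
                     seed: int | np.random.Generator = 0,
                     alternative: str = "greater") -> NullCorrelationResult:
    """Empirical p-value of the observed correlation under an ARIMA null.

    Simulates ``n_sim`` independent pairs (one series from each fitted
    model), differences each by its own d, correlates them index-paired,
    and refers ``r_observed`` to this null with the +1 correction:
    p = (1 + #{r_null >= r_obs}) / (n_sim + 1) for the default one-sided
    (positive-correlation) alternative.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    length = n_days - max(spec_a.d, spec_b.d)
    if length < 3:
        raise ValueError("overlap too short after differencing")
    sims_a = np.empty((n_sim, length))
    sims_b = np.empty((n_sim, length))
    for i in range(n_sim):
        xa = difference_to_stationary(simulate_arima(spec_a, n_days, rng), spec_a.d)
        xb = difference_to_stationary(simulate_arima(spec_b, n_days, rng), spec_b.d)
        sims_a[i] = xa[-length:]
        sims_b[i] = xb[-length:]
    null_r = _corr_rows(sims_a, sims_b)
    if alternative == "greater":
        extreme = np.sum(null_r >= r_observed)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(null_r) >= abs(r_observed))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1.0 + extreme) / (n_sim + 1.0)
    return NullCorrelationResult(r_observed=r_observed, null_r=null_r,
                                 p_value=float(p), n_overlap=n_days)


# ---------------------------------------------------------------------------
# chi-square count comparison and label verification


def compare_drift_counts(n1: int, n2: int) -> tuple[float, int, float]:
    """Two-cell Pearson goodness-of-fit test of drift-dive counts.

    Against equal expected counts e = (n1+n2)/2, without continuity
    correction: chi2 = (n1-e)^2/e + (n2-e)^2/e on 1 d.f.; returns
    (chi2, df, upper-tail p).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 == 0:
        raise ValueError("undefined test: both counts zero")
    e = (n1 + n2) / 2.0
    chi2 = (n1 - e) ** 2 / e + (n2 - e) ** 2 / e
    return float(chi2), 1, float(stats.chi2.sf(chi2, df=1))


def verify_against_labels(drift_fragments: pd.DataFrame,
                          labels: pd.DataFrame) -> VerificationSummary:
    """Per-dive verification of selected drift fragments against labels.

    A selected dive is confirmed iff its label is drift-type; drift-type
    dives never selected count as missed.
    """
    by_dive = labels.set_index(labels["dive_id"].astype(str))["dive_type"]
    selected = set(drift_fragments["dive_id"].astype(str))
    unknown = selected - set(by_dive.index)
    if unknown:
        raise ValueError(f"fragment references unknown dive_id(s): "
                         f"{sorted(unknown)[:5]}")
    confirmed = sum(1 for d in selected if by_dive[d] == "drift")
    drift_dives = set(by_dive.index[by_dive == "drift"])
    return VerificationSummary(
        n_selected=len(selected),
        n_confirmed=confirmed,
        n_false_positive=len(selected) - confirmed,
        n_missed=len(drift_dives - selected),
    )


# ---------------------------------------------------------------------------
# paired-series generator for verification experiments


def simulate_verification_pair(n_days: int, trajectory=None,
                               latent_sd: float = 0.05,
                               latent_phi: float = 0.7,
                               noise_sd: float = 0.015,
                               rng: np.random.Generator | int = 0,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Two daily series observing the same animal's drift rate.

    Emulates the filtered-vs-visually-confirmed verification setting:
    both methods measure the SAME dives, so they share the latent daily
    drift rate (a slow buoyancy trajectory plus AR(1) day-to-day
    fluctuation) and differ only by independent measurement noise.
    """
    from .divesim import BuoyancyTrajectory
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    trajectory = trajectory or BuoyancyTrajectory()
    days = np.arange(n_days, dtype=float)
    trend = trajectory.value(days)
    innov = rng.normal(0.0, latent_sd * np.sqrt(1 - latent_phi ** 2), n_days)
    wiggle = signal.lfilter([1.0], [1.0, -latent_phi], innov)
    latent = trend + wiggle
    a = latent + rng.normal(0.0, noise_sd, n_days)
    b = latent + rng.normal(0.0, noise_sd, n_days)
    return a, b
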