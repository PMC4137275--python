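"""Locomotor-activity rhythm analysis from binned wheel-running actograms.

Three quantities are extracted:

* the free-running period, by the chi-squared periodogram
  (Sokolove-Bushell): for each trial period ``P`` (a whole number of
  bins) the record is folded into ``K`` complete cycles and

      Q_P = K * sum_h (M_h - M)^2 / s^2,

  where ``M_h`` are the column means of the folded array, ``M`` the grand
  mean and ``s^2`` the total variance of the folded samples; under an
  i.i.d. null ``Q_P`` is asymptotically chi-squared with ``P - 1``
  degrees of freedom, and the best period maximizes the excess of ``Q_P``
  over its critical value;
* daily activity onsets, as the first sustained threshold crossing of
  the smoothed activity following a quiet interval;
* days to re-entrain after an imposed shift of the light schedule, as
  the first day from which the onset stays within a tolerance of the
  shifted steady-state phase for a run of consecutive days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

__all__ = [
    "ChiSquarePeriodogram",
    "OnsetDetector",
    "ReentrainmentResult",
    "chi_square_periodogram",
    "detect_onsets",
    "days_to_reentrain",
]


def _counts_and_bin(actogram, bin_min: float | None) -> tuple[np.ndarray, float]:
    if isinstance(actogram, pd.DataFrame):
        counts = actogram["counts"].to_numpy(float)
        if bin_min is None:
            ts = actogram["timestamp_min"].to_numpy(float)
            bin_min = float(ts[1] - ts[0])
    else:
        counts = np.asarray(actogram, dtype=float)
        if bin_min is None:
            raise ValueError("bin_min is required for a bare count array")
    return counts, float(bin_min)


def chi_square_periodogram(
    actogram,
    period_lo: float = 20.0,
    period_hi: float = 30.0,
    bin_min: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chi-squared periodogram over all whole-bin periods in the band.

    Returns a DataFrame (period_h, q, p, critical) whose attrs carry
    ``best_period_h``.  Only complete cycles are folded; the trailing
    partial cycle is dropped.  Raises on a zero-variance record.
    """
    counts, bin_min = _counts_and_bin(actogram, bin_min)
    if np.ptp(counts) == 0:
        raise ValueError("no activity (zero-variance actogram)")
    bin_h = bin_min / 60.0
    lo_bins = max(2, int(math.ceil(period_lo / bin_h)))
    hi_bins = int(math.floor(period_hi / bin_h))
    n = counts.size
    if n // lo_bins < 1 or hi_bins < lo_bins:
        raise ValueError("record too short for the requested period band")

    rows = []
    for P in range(lo_bins, hi_bins + 1):
        K = n // P
        if K < 1:
            break
        x = counts[: K * P]
        folded = x.reshape(K, P)
        col_means = folded.mean(axis=0)
        grand = x.mean()
        s2 = np.mean((x - grand) ** 2)
        q = K * np.sum((col_means - grand) ** 2) / s2
        rows.append((P * bin_h, q, chi2.sf(q, P - 1), chi2.ppf(1 - alpha, P - 1)))
    out = pd.DataFrame(rows, columns=["period_h", "q", "p", "critical"])
    best = out.loc[(out["q"] - out["critical"]).idxmax(), "period_h"]
    out.attrs["best_period_h"] = float(best)
    return out


class ChiSquarePeriodogram(BaseEstimator):
    """Chi-squared periodogram estimator of the free-running period.

    Attributes after ``fit``: ``periodogram_`` (period_h, q, p, critical)
    and ``best_period_`` in hours.
    """

    def __init__(self, period_lo: float = 20.0, period_hi: float = 30.0,
                 alpha: float = 0.05):
        self.period_lo = period_lo
        self.period_hi = period_hi
        self.alpha = alpha

    def fit(self, X, y=None, bin_min: float | None = None):
        self.periodogram_ = chi_square_periodogram(
            X, self.period_lo, self.period_hi, bin_min=bin_min, alpha=self.alpha
        )
        self.best_period_ = self.periodogram_.attrs["best_period_h"]
        return self


def _moving_average(x: np.ndarray, window_bins: int) -> np.ndarray:
    if window_bins <= 1:
        return x.astype(float)
    kernel = np.ones(window_bins) / window_bins
    pad = window_bins // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return sm


def detect_onsets(
    actogram,
    smoothing_window_min: float = 30.0,
    threshold_frac: float = 0.2,
    quiet_hours: float = 4.0,
    bin_min: float | None = None,
) -> pd.DataFrame:
    """Daily activity onsets from a binned actogram.

    For each calendar day the candidate onset is the start of the first
    run where the smoothed activity exceeds ``threshold_frac`` times that
    day's smoothed maximum after at least ``quiet_hours`` of sub-threshold
    smoothed activity; the reported onset is then refined to the first raw
    bin at threshold in the candidate's neighbourhood.  Days without a
    qualifying crossing get a NaN gap record.  The returned DataFrame
    (day, onset_h, with onset hours within the day) carries the fitted
    linear drift (h/day, NaN-robust, phase-unwrapped) in
    ``attrs['drift_h_per_day']``.
    """
    counts, bin_min = _counts_and_bin(actogram, bin_min)
    bin_h = bin_min / 60.0
    per_day = int(round(24.0 / bin_h))
    if per_day * bin_h != 24.0:
        raise ValueError("bin width must divide 24 h")
    n_days = counts.size // per_day
    window_bins = max(1, int(round(smoothing_window_min / bin_min)))
    quiet_bins = int(round(quiet_hours / bin_h))
    smoothed = _moving_average(counts, window_bins)

    onsets = np.full(n_days, np.nan)
    for d in range(n_days):
        sl = slice(d * per_day, (d + 1) * per_day)
        day_max = smoothed[sl].max()
        if day_max <= 0:
            continue
        thr = threshold_frac * day_max
        above = smoothed[sl] >= thr
        idx = None
        for i in np.flatnonzero(above):
            g = d * per_day + i
            pre = smoothed[max(0, g - quiet_bins) : g]
            if pre.size == 0 or np.all(pre < thr):
                idx = i
                break
        if idx is None:
            continue
        # refine: first raw bin at threshold from just before the smoothed crossing
        start = max(0, d * per_day + idx - window_bins)
        stop = min(counts.size, d * per_day + idx + window_bins + 1)
        raw_hits = np.flatnonzero(counts[start:stop] >= thr)
        g = start + raw_hits[0] if raw_hits.size else d * per_day + idx
        onsets[d] = (g % per_day) * bin_h

    out = pd.DataFrame({"day": np.arange(n_days), "onset_h": onsets})
    ok = ~np.isnan(onsets)
    drift = np.nan
    if ok.sum() >= 2:
        ang = np.unwrap(onsets[ok] * (2 * np.pi / 24.0))
        drift = float(np.polyfit(np.flatnonzero(ok), ang, 1)[0] * 24.0 / (2 * np.pi))
    out.attrs["drift_h_per_day"] = drift
    return out


class OnsetDetector(BaseEstimator):
    """Activity-onset detector; after ``fit``: ``onsets_`` and ``drift_``."""

    def __init__(self, smoothing_window_min: float = 30.0,
                 threshold_frac: float = 0.2, quiet_hours: float = 4.0):
        self.smoothing_window_min = smoothing_window_min
        self.threshold_frac = threshold_frac
        self.quiet_hours = quiet_hours

    def fit(self, X, y=None, bin_min: float | None = None):
        self.onsets_ = detect_onsets(
            X, self.smoothing_window_min, self.threshold_frac,
            self.quiet_hours, bin_min=bin_min,
        )
        self.drift_ = self.onsets_.attrs["drift_h_per_day"]
        return self


@dataclass
class ReentrainmentResult:
    days: int | None            # None when the record never re-entrains
    reentrained: bool
    days_observed: int
    target_phase_h: float


def _circdiff_h(a: float, b: float) -> float:
    """Signed circular difference a - b in hours, in [-12, 12)."""
    return (a - b + 12.0) % 24.0 - 12.0


def days_to_reentrain(
    onsets: pd.DataFrame | np.ndarray,
    shift_h: float,
    shift_day: int,
    tolerance_h: float = 0.5,
    consecutive_days: int = 3,
) -> ReentrainmentResult:
    """Days needed for the activity onset to settle at the shifted phase.

    ``shift_h`` is the signed change of onset time (an 8-h advance of the
    light schedule is ``-8``).  The pre-shift steady state is the circular
    mean onset over days before ``shift_day``; the answer is the smallest
    ``d >= 1`` such that on days ``shift_day+d .. shift_day+d+c-1`` every
    onset is present and within ``tolerance_h`` of target.
    """
    if isinstance(onsets, pd.DataFrame):
        onset_h = onsets["onset_h"].to_numpy(float)
    else:
        onset_h = np.asarray(onsets, dtype=float)
    if onset_h.size < shift_day + 2:
        raise ValueError("onset record must span at least shift_day + 2 days")
    pre = onset_h[:shift_day]
    pre = pre[~np.isnan(pre)]
    if pre.size == 0:
        raise ValueError("no pre-shift onsets to define the baseline phase")
    ang = pre * (2 * np.pi / 24.0)
    base = math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) * 24.0 / (2 * np.pi)
    target = (base + shift_h) % 24.0

    n_days = onset_h.size
    for d in range(1, n_days - shift_day - consecutive_days + 2):
        window = onset_h[shift_day + d : shift_day + d + consecutive_days]
        if window.size < consecutive_days or np.any(np.isnan(window)):
            continue
        if np.all(np.abs([_circdiff_h(o, target) for o in window]) <= tolerance_h):
            return ReentrainmentResult(d, True, n_days, target)
    return ReentrainmentResult(None, False, n_days, target)
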