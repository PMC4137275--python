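"""Phase extraction and synchrony statistics for multiunit activity (MUA).

Multielectrode recordings of SCN slices yield one firing-rate trace per
channel.  Each channel is min-max normalized, binned to 1 h, smoothed
with a centered moving average and fitted per 24-h day with a sinusoid
``a + b*cos(2*pi*(t - theta)/24)``; the fitted peak time ``theta`` (mod
24 h) is the channel's daily phase.  Cross-channel synchrony on a day is
summarized by the circular resultant length

    R = | mean_c exp(i * 2*pi*theta_c / 24) |,

which is 1 when all phases coincide and 0 under antipodal or uniform
dispersion; the circular SD is ``sqrt(-2 ln R)`` converted to hours.
Flat and monotonically decreasing channels are excluded before analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ChannelPhase",
    "SynchronyStats",
    "PhaseSynchronyAnalyzer",
    "normalize_and_bin",
    "peak_phases",
    "synchrony_index",
    "synchrony_trajectory",
]

_HOURS_PER_RAD = 24.0 / (2.0 * np.pi)


@dataclass
class ChannelPhase:
    channel: str
    day: int
    phase_h: float       # peak time, circadian hours in [0, 24)
    amplitude: float     # fitted amplitude on the normalized trace
    fit_ok: bool


@dataclass
class SynchronyStats:
    day: int
    mean_phase_h: float
    resultant_length: float
    circular_sd_h: float
    n_channels: int


def normalize_and_bin(
    recording: pd.DataFrame,
    bin_h: float = 1.0,
    flat_tol: float = 1e-10,
) -> pd.DataFrame:
    """Min-max normalize each channel to [0, 1], then mean-bin to ``bin_h``.

    Channels that are flat (range below ``flat_tol`` relative to their
    mean) or monotonically decreasing over the whole recording are
    excluded with a warning, mirroring standard electrode quality control.
    """
    t = np.asarray(recording.index, dtype=float)
    if t.size < 2:
        raise ValueError("recording too short")
    dt = t[1] - t[0]
    per_bin = int(round(bin_h / dt))
    if per_bin < 1 or abs(per_bin * dt - bin_h) > 1e-9:
        raise ValueError("bin_h must be a multiple of the sampling interval")

    keep = []
    for ch in recording.columns:
        x = recording[ch].to_numpy(float)
        rng_ = np.ptp(x)
        if rng_ <= flat_tol * (1.0 + abs(x.mean())):
            warnings.warn(f"excluding flat channel {ch!r}")
            continue
        d = np.diff(x)
        if np.all(d <= 0) and x[0] > x[-1]:
            warnings.warn(f"excluding monotonically decreasing channel {ch!r}")
            continue
        keep.append(ch)
    if not keep:
        raise ValueError("no usable channels after exclusion")

    X = recording[keep].to_numpy(float)
    X = (X - X.min(axis=0)) / np.ptp(X, axis=0)
    n_bins = X.shape[0] // per_bin
    Xb = X[: n_bins * per_bin].reshape(n_bins, per_bin, -1).mean(axis=1)
    tb = t[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    return pd.DataFrame(Xb, index=pd.Index(tb, name="time_h"), columns=keep)


def _fit_cos24(t: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """LSQ fit of a + b*cos(wt) + c*sin(wt), w = 2*pi/24.

    Returns (phase_h in [0, 24), amplitude, residual RMS).
    """
    w = 2.0 * np.pi / 24.0
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ coef
    amp = float(np.hypot(coef[1], coef[2]))
    phase = float(np.mod(math.atan2(coef[2], coef[1]) * _HOURS_PER_RAD, 24.0))
    rms = float(np.sqrt(np.mean(resid**2)))
    return phase, amp, rms


def peak_phases(
    normalized: pd.DataFrame,
    day: int,
    smoothing_h: float = 3.0,
    min_bins: int = 18,
    quality_floor: float = 1.0,
) -> list[ChannelPhase]:
    """Per-channel peak phase on one 24-h day by sinusoid fitting.

    The day's hourly bins are smoothed with a centered moving average of
    ``smoothing_h`` before fitting a fixed-period (24 h) cosinor; the fit
    is flagged not-OK when the amplitude/residual-RMS ratio falls below
    ``quality_floor``.  Fewer than ``min_bins`` bins yield a gap record
    (``fit_ok=False``, NaN phase).
    """
    t = np.asarray(normalized.index, dtype=float)
    sel = (t >= 24.0 * day) & (t < 24.0 * (day + 1))
    out: list[ChannelPhase] = []
    bin_h = t[1] - t[0] if t.size > 1 else 1.0
    win = max(1, int(round(smoothing_h / bin_h)))
    kernel = np.ones(win) / win
    for ch in normalized.columns:
        x = normalized.loc[sel, ch].to_numpy(float)
        td = t[sel]
        if td.size < min_bins:
            out.append(ChannelPhase(str(ch), day, float("nan"), 0.0, False))
            continue
        pad = win // 2
        xs = np.convolve(np.pad(x, pad, mode="wrap"), kernel, mode="same")
        xs = xs[pad : pad + x.size]
        phase, amp, _ = _fit_cos24(td, xs)
        # fit quality against the raw (unsmoothed) data: smoothing deflates
        # the residual and would let white-noise channels pass the floor
        w = 2.0 * np.pi / 24.0
        model = (xs.mean() - amp * np.mean(np.cos(w * (td - phase)))) \
            + amp * np.cos(w * (td - phase))
        rms = float(np.sqrt(np.mean((x - model) ** 2)))
        ok = (amp / rms) >= quality_floor if rms > 0 else amp > 0
        out.append(ChannelPhase(str(ch), day, phase, amp, bool(ok)))
    return out


def synchrony_index(phases) -> SynchronyStats:
    """Circular mean, resultant length R and circular SD of daily phases.

    Accepts a list of :class:`ChannelPhase` (only ``fit_ok`` records are
    used) or a bare array of phases in hours.
    """
    if len(phases) and isinstance(phases[0], ChannelPhase):
        day = phases[0].day
        vals = np.array([p.phase_h for p in phases if p.fit_ok], dtype=float)
    else:
        day = 0
        vals = np.asarray(phases, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 usable channel phases")
    ang = vals / _HOURS_PER_RAD
    z = np.exp(1j * ang).mean()
    R = float(np.abs(z))
    mean_h = float(np.mod(np.angle(z) * _HOURS_PER_RAD, 24.0))
    sd_h = float(np.sqrt(-2.0 * np.log(R)) * _HOURS_PER_RAD) if R > 0 else float("inf")
    return SynchronyStats(day, mean_h, R, sd_h, int(vals.size))


def synchrony_trajectory(
    recording: pd.DataFrame,
    days: int | None = None,
    rescue_schedule=None,
    bin_h: float = 1.0,
    smoothing_h: float = 3.0,
    quality_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-day synchrony statistics over a multi-day recording.

    Returns a DataFrame (day, mean_phase_h, R, circular_sd_h, n_channels,
    rescue_event); the rescue schedule only annotates rows — the analysis
    itself is passive.
    """
    norm = normalize_and_bin(recording, bin_h=bin_h)
    t = np.asarray(norm.index, dtype=float)
    if days is None:
        days = int(t.max() // 24.0) + 1
    events = set(rescue_schedule or [])
    rows = []
    for d in range(days):
        ph = peak_phases(norm, d, smoothing_h=smoothing_h,
                         quality_floor=quality_floor)
        stats = synchrony_index(ph)
        rows.append((d, stats.mean_phase_h, stats.resultant_length,
                     stats.circular_sd_h, stats.n_channels, d in events))
    return pd.DataFrame(
        rows,
        columns=["day", "mean_phase_h", "R", "circular_sd_h",
                 "n_channels", "rescue_event"],
    )


class PhaseSynchronyAnalyzer(BaseEstimator):
    """Daily peak-phase and synchrony analysis of an MUA recording.

    Attributes after ``fit``: ``normalized_`` (hourly normalized matrix),
    ``phases_`` (long DataFrame of per-channel daily phases) and
    ``synchrony_`` (per-day SynchronyStats table).
    """

    def __init__(self, bin_h: float = 1.0, smoothing_h: float = 3.0,
                 quality_floor: float = 1.0):
        self.bin_h = bin_h
        self.smoothing_h = smoothing_h
        self.quality_floor = quality_floor

    def fit(self, X: pd.DataFrame, y=None, days: int | None = None,
            rescue_schedule=None):
        norm = normalize_and_bin(X, bin_h=self.bin_h)
        t = np.asarray(norm.index, dtype=float)
        n_days = days if days is not None else int(t.max() // 24.0) + 1
        recs = []
        for d in range(n_days):
            recs.extend(peak_phases(norm, d, smoothing_h=self.smoothing_h,
                                    quality_floor=self.quality_floor))
        self.normalized_ = norm
        self.phases_ = pd.DataFrame(
            [(p.channel, p.day, p.phase_h, p.amplitude, p.fit_ok) for p in recs],
            columns=["channel", "day", "phase_h", "amplitude", "fit_ok"],
        )
        self.synchrony_ = synchrony_trajectory(
            X, days=n_days, rescue_schedule=rescue_schedule, bin_h=self.bin_h,
            smoothing_h=self.smoothing_h, quality_floor=self.quality_floor,
        )
        return self
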