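"""Synthetic data generators with planted ground truth.

Every input the screening pipeline consumes can be generated here under a
controlled design:

* a circadian expression time course (24 samples every 2 h over 48 h of
  constant darkness, starting at CT18) with a planted fraction of cycling
  probesets;
* paired light/dark expression tables for the 9 light-pulse conditions
  (pulses beginning at CT30/CT40/CT46, samples 1/2/4 h after pulse start)
  with planted induced/suppressed fold effects;
* a multi-tissue expression atlas (82 tissues in duplicate plus a single
  SCN summary column) with planted SCN-enriched probesets;
* wheel-running actograms in 5-min bins under LD/DD schedules with a
  free-running period, optional phase shift and re-entrainment rate;
* multiunit-activity recordings (channels x time) whose per-channel peak
  phases can disperse over days and re-contract at scheduled events
  (phenomenological stand-in for daily neuropeptide application).

Measurement noise is multiplicative log-normal with a configurable
coefficient of variation (intensities are positive and array-like); each
generator is fully determined by its design and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircadianDesign",
    "AtlasDesign",
    "LIGHT_CONDITIONS",
    "condition_label",
    "generate_circadian_timecourse",
    "generate_light_pulse_set",
    "random_light_effects",
    "generate_tissue_atlas",
    "generate_actogram",
    "generate_mua",
    "ActogramResult",
    "MUAResult",
    "AtlasResult",
]

#: The 9 light-pulse conditions: (pulse start CT, hours after pulse start).
LIGHT_CONDITIONS: tuple[tuple[int, int], ...] = (
    (30, 1), (30, 2), (30, 4),
    (40, 1), (40, 2), (40, 4),
    (46, 1), (46, 2), (46, 4),
)


def condition_label(pulse_ct: int, post_h: int) -> str:
    return f"CT{pulse_ct}+{post_h}h"


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


@dataclass
class CircadianDesign:
    """Design of the circadian time-course experiment.

    Defaults follow the 2-h / 48-h constant-darkness sampling design
    starting at CT18, with planted cyclers at relative amplitude 0.5 over
    a log-normal baseline and 15% multiplicative measurement noise.
    """

    n_probesets: int = 1000
    start_ct: float = 18.0
    spacing: float = 2.0
    n_samples: int = 24
    frac_cyclers: float = 0.3
    period_range: tuple[float, float] = (20.0, 30.0)
    amplitude_rel: float = 0.5
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.5
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_cyclers <= 1):
            raise ValueError("frac_cyclers must lie in [0, 1]")
        if not (0 <= self.amplitude_rel < 1):
            raise ValueError(
                "amplitude_rel must lie in [0, 1): larger values allow "
                "non-positive intensities"
            )
        if self.baseline_log_sd < 0 or self.noise_cv < 0:
            raise ValueError("dispersion parameters must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.start_ct + self.spacing * np.arange(self.n_samples)

    @property
    def columns(self) -> list[str]:
        return [f"CT{t:g}" for t in self.times]


def _probeset_ids(n: int) -> pd.Index:
    return pd.Index([f"ps_{i:05d}" for i in range(n)], name="probeset")


def _plant_gene_params(design: CircadianDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_probesets
    baseline = np.exp(rng.normal(design.baseline_log_mean, design.baseline_log_sd, n))
    n_cyc = int(round(design.frac_cyclers * n))
    is_cycler = np.zeros(n, dtype=bool)
    is_cycler[rng.choice(n, size=n_cyc, replace=False)] = True
    lo, hi = design.period_range
    period = np.where(is_cycler, rng.uniform(lo, hi, n), np.nan)
    phase = np.where(is_cycler, rng.uniform(0.0, 24.0, n), np.nan)
    amplitude = np.where(is_cycler, design.amplitude_rel * baseline, 0.0)
    return pd.DataFrame(
        {
            "is_cycler": is_cycler,
            "true_period": period,
            "true_phase": phase,
            "true_amplitude": amplitude,
            "baseline": baseline,
        },
        index=_probeset_ids(n),
    )


def _trajectory(truth: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Noise-free expression of every probeset at the given times."""
    base = truth["baseline"].to_numpy()[:, None]
    signal = np.repeat(base, len(times), axis=1).astype(float)
    cyc = truth["is_cycler"].to_numpy()
    if cyc.any():
        tau = truth.loc[cyc, "true_period"].to_numpy()[:, None]
        phi = truth.loc[cyc, "true_phase"].to_numpy()[:, None]
        amp = truth.loc[cyc, "true_amplitude"].to_numpy()[:, None]
        signal[cyc] = base[cyc] + amp * np.cos(2 * np.pi * (times[None, :] - phi) / tau)
    return signal


def generate_circadian_timecourse(
    design: CircadianDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a probesets x samples intensity matrix and its ground truth.

    Cyclers follow ``baseline * (1 + amplitude_rel*cos(2*pi*(t-phase)/period))``
    under multiplicative log-normal noise; non-cyclers are flat baselines
    plus the same noise.
    """
    rng = np.random.default_rng(design.seed)
    truth = _plant_gene_params(design, rng)
    signal = _trajectory(truth, design.times)
    values = signal * _lognormal_factors(rng, design.noise_cv, signal.shape)
    matrix = pd.DataFrame(values, index=truth.index, columns=design.columns)
    return matrix, truth


def random_light_effects(
    probesets: Sequence[str],
    n_induced: int,
    n_suppressed: int,
    fold_induced: float = 3.0,
    fold_suppressed: float = 0.25,
    conditions_per_gene: int = 3,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Plant induced/suppressed fold effects on disjoint random gene sets.

    Each affected gene gets its fold multiplier at ``conditions_per_gene``
    randomly chosen conditions (all 9 if the count exceeds 9).
    """
    rng = np.random.default_rng(seed)
    probesets = list(probesets)
    chosen = rng.choice(len(probesets), size=n_induced + n_suppressed, replace=False)
    labels = [condition_label(*c) for c in LIGHT_CONDITIONS]
    k = min(conditions_per_gene, len(labels))
    effects: dict[str, dict[str, float]] = {}
    for rank, idx in enumerate(chosen):
        fold = fold_induced if rank < n_induced else fold_suppressed
        conds = rng.choice(len(labels), size=k, replace=False)
        effects[probesets[idx]] = {labels[c]: fold for c in conds}
    return effects


def generate_light_pulse_set(
    design: CircadianDesign,
    effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired light/dark means for the 9 light-pulse conditions.

    Dark values are sampled from each gene's circadian trajectory at the
    collection times (pulse CT + 1/2/4 h); light values multiply the same
    trajectory value by the planted per-condition fold (1 elsewhere).
    Light and dark cohorts receive independent measurement noise.

    Returns a DataFrame with MultiIndex columns ``(condition, 'light'|'dark')``
    and a ground-truth table of per-condition fold effects and classes.
    """
    effects = effects or {}
    for gene, m in effects.items():
        for cond, fold in m.items():
            if fold <= 0:
                raise ValueError(f"fold multiplier must be positive ({gene}, {cond})")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    truth = _plant_gene_params(design, rng)
    labels = [condition_label(*c) for c in LIGHT_CONDITIONS]
    sample_times = np.array([ct + h for ct, h in LIGHT_CONDITIONS], dtype=float)
    dark_signal = _trajectory(truth, sample_times)

    folds = pd.DataFrame(1.0, index=truth.index, columns=labels)
    for gene, m in effects.items():
        if gene not in folds.index:
            raise KeyError(f"unknown probeset {gene!r}")
        for cond, fold in m.items():
            if cond not in folds.columns:
                raise KeyError(f"unknown condition {cond!r}")
            folds.loc[gene, cond] = fold

    dark = dark_signal * _lognormal_factors(rng, design.noise_cv, dark_signal.shape)
    light = (
        dark_signal
        * folds.to_numpy()
        * _lognormal_factors(rng, design.noise_cv, dark_signal.shape)
    )
    pairs = pd.DataFrame(
        np.column_stack([np.column_stack([light[:, i], dark[:, i]]) for i in range(9)]),
        index=truth.index,
        columns=pd.MultiIndex.from_product([labels, ["light", "dark"]],
                                           names=["condition", "arm"]),
    )
    classes = pd.DataFrame("none", index=truth.index, columns=labels)
    classes = classes.where(folds < 2.0, "induced").where(folds > 0.5, "suppressed")
    light_truth = pd.concat(
        [folds.add_prefix("fold:"), classes.add_prefix("class:")], axis=1
    )
    light_truth["any_induced"] = (classes == "induced").any(axis=1)
    light_truth["any_suppressed"] = (classes == "suppressed").any(axis=1)
    return pairs, light_truth


@dataclass
class AtlasDesign:
    """Design of the multi-tissue expression atlas.

    83 tissues including the SCN; every non-SCN tissue contributes a
    duplicate pair of columns while the SCN contributes a single summary
    column (the per-probeset median of the 24 circadian samples).
    """

    n_tissues: int = 83
    n_neural: int = 14
    replicates: int = 2
    frac_enriched: float = 0.05
    enrichment_factor: float = 10.0
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates != 2:
            raise ValueError("enrichment formulas assume 82 x 2 + 1 columns")
        if self.n_neural < 1 or self.n_neural >= self.n_tissues:
            raise ValueError("need 1 <= n_neural < n_tissues")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be positive")

    def tissue_table(self) -> pd.DataFrame:
        """Per-column tissue metadata; hypothalamus is the first neural tissue."""
        rows = []
        n_other = self.n_tissues - 1  # non-SCN tissues
        for i in range(n_other):
            if i == 0:
                name, neural, hyp = "hypothalamus", True, True
            elif i < self.n_neural:
                name, neural, hyp = f"neural_{i + 1:02d}", True, False
            else:
                name, neural, hyp = f"tissue_{i + 1:02d}", False, False
            for r in (1, 2):
                rows.append((f"{name}_r{r}", name, r, neural, hyp, False))
        rows.append(("SCN", "SCN", 1, True, False, True))
        return pd.DataFrame(
            rows,
            columns=["column", "tissue", "replicate", "is_neural",
                     "is_hypothalamus", "is_scn"],
        ).set_index("column")


class AtlasResult(NamedTuple):
    values: pd.DataFrame
    tissues: pd.DataFrame
    truth: pd.DataFrame


def generate_tissue_atlas(
    design: AtlasDesign,
    timecourse: pd.DataFrame,
) -> AtlasResult:
    """Generate the tissue atlas around an existing circadian time course.

    The SCN column is the per-probeset median of the 24 circadian samples.
    For an enriched probeset the non-SCN tissues sit ``enrichment_factor``
    below the SCN value; for other probesets they match it.  Replicate
    pairs differ only by measurement noise.
    """
    if timecourse.shape[1] != 24:
        raise ValueError("timecourse must provide exactly 24 circadian samples")
    rng = np.random.default_rng(design.seed)
    scn = timecourse.median(axis=1).to_numpy()
    n = len(timecourse)
    enriched = np.zeros(n, dtype=bool)
    n_enr = int(round(design.frac_enriched * n))
    enriched[rng.choice(n, size=n_enr, replace=False)] = True
    background = np.where(enriched, scn / design.enrichment_factor, scn)

    meta = design.tissue_table()
    other_cols = meta.index[~meta["is_scn"]]
    vals = background[:, None] * _lognormal_factors(
        rng, design.noise_cv, (n, len(other_cols))
    )
    values = pd.DataFrame(vals, index=timecourse.index, columns=other_cols)
    values["SCN"] = scn
    truth = pd.DataFrame(
        {
            "is_scn_enriched": enriched,
            "enrichment_factor": np.where(enriched, design.enrichment_factor, 1.0),
        },
        index=timecourse.index,
    )
    return AtlasResult(values, meta, truth)


class ActogramResult(NamedTuple):
    data: pd.DataFrame           # timestamp_min, counts, lights_on
    true_onsets_h: np.ndarray    # per-day activity onset, absolute hours


def generate_actogram(
    schedule: str = "DD",
    tau: float = 23.6,
    n_days: int = 14,
    bin_min: int = 5,
    shift_h: float = 0.0,
    shift_day: int | None = None,
    reentrain_rate: float = 1.0,
    onset_noise_sd: float = 0.0,
    bout_h: float = 10.0,
    rate_active: float = 20.0,
    rate_rest: float = 0.2,
    lights_off_h: float = 12.0,
    onset0_h: float = 12.0,
    deterministic: bool = False,
    seed: int = 0,
) -> ActogramResult:
    """Generate a wheel-running actogram in 5-min bins.

    Under ``schedule='LD'`` the nightly activity onset locks to lights-off
    (``lights_off_h`` each day); under ``'DD'`` it free-runs, advancing or
    delaying by ``tau - 24`` h/day.  An imposed LD shift of ``shift_h``
    (signed change of onset time; advance is negative) at ``shift_day``
    moves the onset ``reentrain_rate`` h/day toward the new phase.  Counts
    are Poisson (``rate_active`` per bin inside a ``bout_h`` activity bout,
    ``rate_rest`` outside) unless ``deterministic`` is set, in which case
    counts equal the rates exactly.
    """
    if (24 * 60) % bin_min != 0:
        raise ValueError("bin width must divide 24 h")
    if schedule not in ("LD", "DD"):
        raise ValueError("schedule must be 'LD' or 'DD'")
    if schedule == "DD" and not (20.0 <= tau <= 28.0):
        raise ValueError("tau must lie in [20, 28] h")
    rng = np.random.default_rng(seed)

    onsets = np.empty(n_days)
    phase = onset0_h if schedule == "DD" else lights_off_h
    for d in range(n_days):
        if schedule == "LD":
            if shift_day is not None and d >= shift_day:
                target = lights_off_h + shift_h
                k = d - shift_day
                delta = target - lights_off_h
                moved = math.copysign(min(reentrain_rate * k, abs(delta)), delta)
                phase = lights_off_h + moved
            else:
                phase = lights_off_h
        onsets[d] = 24.0 * d + phase
        if schedule == "DD":
            phase += tau - 24.0
    if onset_noise_sd > 0:
        onsets = onsets + rng.normal(0.0, onset_noise_sd, n_days)

    n_bins = n_days * 24 * 60 // bin_min
    t_min = bin_min * np.arange(n_bins)
    t_h = t_min / 60.0
    active = np.zeros(n_bins, dtype=bool)
    for o in onsets:
        active |= (t_h >= o) & (t_h < o + bout_h)
    rates = np.where(active, rate_active, rate_rest)
    counts = rates if deterministic else rng.poisson(rates).astype(float)

    lights_on = np.zeros(n_bins, dtype=bool)
    if schedule == "LD":
        day = t_h % 24.0
        lights_on = (day >= lights_off_h - 12.0) & (day < lights_off_h)
        if shift_day is not None:
            after = t_h >= 24.0 * shift_day
            day_s = (t_h - shift_h) % 24.0
            lights_on = np.where(
                after,
                (day_s >= lights_off_h - 12.0) & (day_s < lights_off_h),
                lights_on,
            )
    data = pd.DataFrame(
        {"timestamp_min": t_min, "counts": counts, "lights_on": lights_on.astype(int)}
    )
    return ActogramResult(data, onsets)


class MUAResult(NamedTuple):
    data: pd.DataFrame        # index time_h, one column per channel
    periods: np.ndarray       # per-channel intrinsic period (h)
    phases: np.ndarray        # (n_days, n_channels) planted peak phase (h, mod 24)


def generate_mua(
    n_channels: int = 40,
    n_days: int = 3,
    period_mean: float = 24.0,
    period_sd: float = 0.0,
    phase_mean: float = 6.0,
    phase_sd: float = 1.0,
    desync_rate: float = 0.0,
    resync_schedule: Sequence[int] | None = None,
    resync_factor: float = 0.5,
    baseline: float = 10.0,
    amplitude_rel: float = 0.8,
    noise_sd: float = 0.0,
    sampling_min: int = 10,
    seed: int = 0,
) -> MUAResult:
    """Generate a multiunit-activity recording (channels x time, firing rate).

    Each channel fires as ``baseline * (1 + amplitude_rel * cos(...))`` with
    channel-specific period (SD ``period_sd``) and initial peak phase
    (SD ``phase_sd`` around ``phase_mean``).  Phases drift apart by a
    per-day Gaussian increment of SD ``desync_rate`` (h/day) plus the
    deterministic drift from the period spread; on each day listed in
    ``resync_schedule`` the phase deviations from the circular mean are
    contracted by ``resync_factor``.  Additive Gaussian noise is clipped
    at zero (clipping is logged as a warning).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(seed)
    periods = rng.normal(period_mean, period_sd, n_channels)
    phases = np.empty((n_days, n_channels))
    phases[0] = rng.normal(phase_mean, phase_sd, n_channels)
    for d in range(1, n_days):
        drift = periods - 24.0
        step = rng.normal(0.0, desync_rate, n_channels) if desync_rate > 0 else 0.0
        phases[d] = phases[d - 1] + drift + step
        if resync_schedule and d in set(resync_schedule):
            ang = phases[d] * (2 * np.pi / 24.0)
            mean_ang = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
            dev = np.angle(np.exp(1j * (ang - mean_ang)))
            phases[d] = (mean_ang + (1.0 - resync_factor) * dev) * 24.0 / (2 * np.pi)

    n_per_day = 24 * 60 // sampling_min
    t_h = (sampling_min / 60.0) * np.arange(n_days * n_per_day)
    rates = np.empty((t_h.size, n_channels))
    for d in range(n_days):
        sl = slice(d * n_per_day, (d + 1) * n_per_day)
        arg = 2 * np.pi * (t_h[sl, None] - phases[d][None, :]) / 24.0
        rates[sl] = baseline * (1.0 + amplitude_rel * np.cos(arg))
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, rates.shape)
        n_clip = int(np.count_nonzero(rates < 0))
        if n_clip:
            warnings.warn(f"clipped {n_clip} negative rate value(s) at 0")
        np.clip(rates, 0.0, None, out=rates)
    data = pd.DataFrame(
        rates,
        index=pd.Index(t_h, name="time_h"),
        columns=[f"ch_{i + 1:02d}" for i in range(n_channels)],
    )
    return MUAResult(data, periods, np.mod(phases, 24.0))
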