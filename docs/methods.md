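# Methods

This note documents the models, the defaults and the design decisions
behind `scnscreen`, and what the synthetic-data validation does and does
not establish about real data.

## Rhythm detection

The temporal profile of a probeset is modelled as a single-harmonic
cosinor, x(t) = M + β·cos(2π(t − φ)/τ) with mesor M, amplitude β ≥ 0,
acrophase φ (peak time, reported mod τ) and period τ. For each τ on a
grid (20–30 h, step 0.1 h — the circadian band; finer steps are wasted
against the period information in a 2-cycle record) the remaining
parameters come from the closed-form linear regression on the
{1, cos ωt, sin ωt} basis; the grid period minimizing the residual sum
of squares wins, ties broken toward 24 h and then toward the smaller
period. A constant series is flagged degenerate: amplitude 0, both
significance tests return p = 1.

Two significance measures:

* **Permutation amplitude test.** The statistic is β̂/SE(β̂), with
  SE from the delta method on the (cos, sin) coefficient covariance,
  maximized over the period grid; the null permutes the sample order
  (B = 1000 by default, seeded per series) and
  p = (1 + #{perm ≥ obs})/(B + 1). The exact internals of the
  historical COSOPT statistic are not published; this definition keeps
  its Monte-Carlo spirit and is exactly calibratable — on white noise
  the rejection rate at α = 0.05 equals the discrete-permutation value
  10/(B+1) (measured 4.9% at B = 200 over 10,000 series).
* **Fisher's exact G-test.** After mean-detrending, g is the largest
  periodogram ordinate over the Fourier frequencies k = 1..m,
  m = ⌊(n−1)/2⌋, divided by their sum; the p-value is the exact
  closed-form null tail. All Fourier frequencies of the 24-point series
  enter; the 20–30 h band requirement is enforced through the cosinor
  period, not by masking G-test frequencies. Whether the historical
  "pFGT" was Fisher's G or an F goodness-of-fit statistic is not
  recorded; Fisher's G is implemented and documented as the
  interpretation.

A cycler must satisfy p_MMCβ < 0.05, p_FGT < 0.05, raw median of the 24
samples > 100 intensity units, and τ̂ ∈ [20, 30] h. No multiple-testing
correction is applied — the screen's cutoffs are raw per-test p-values.
The median filter uses raw sample values, not fitted ones. Unweighted
fits are used throughout (no per-sample measurement SDs exist in the
input format).

**Accuracy at the study conditions.** With relative amplitude 0.5 and
15% multiplicative noise, the median period error of the grid cosinor is
0.4–0.5 h — close to the information limit of a 48-h (≈2-cycle) record
at that signal-to-noise ratio — and the median peak-time error is
≈0.25 h. Peak-time (acrophase) recovery is measured at the fitted peak
nearest the center of the sampling window: with any period error, the
phase is only identified within the sampled interval, and anchoring the
comparison at absolute time zero (41 h outside the window) would measure
period extrapolation rather than phase recovery.

## Light response

Fold change is the ratio of pre-averaged light and dark condition means,
in the fixed condition order (CT30: +1, +2, +4 h; CT40: ditto; CT46:
ditto). Values below a floor of 1 intensity unit are raised to it on
both arms before forming ratios — near-background array intensities are
unreliable and unfloored ratios explode; flooring both arms keeps the
light↔dark swap symmetry exact. Induced means FC ≥ cutoff (default 2,
inclusive), suppressed FC ≤ 1/cutoff; a probeset may be induced at one
condition and suppressed at another, and "light-regulated" is
any-condition. No replicate-level statistics are computed: the design
consumes pre-averaged means, so classification is a pure threshold rule.

## Tissue enrichment

Z(all) is computed on the raw 165-value vector (82 tissues × 2
replicates + the SCN summary, which is included in the vector following
the stated 82×2+1 count), Z(neural) on the 29-value vector (14 neural
tissues × 2 + SCN). The SCN summary value is the median of the
probeset's 24 circadian samples (even-count median = mean of the two
central order statistics). The standard deviation defaults to the
sample (n−1) form and is configurable (`ddof=0` for the population
form); the source convention is not recorded. The hypothalamus
denominator is the mean of its duplicate pair. Threshold semantics are
inclusive (≥) for the three scores and strict (>) for the median floor.
Shortlists are ordered by descending Z(all) for determinism.

Tissue clustering uses 1 − Pearson correlation between
replicate-averaged tissue profiles with average linkage — the
conventional transcriptome-atlas default — and exports the dendrogram
as Newick. Zero-variance tissue profiles are excluded with a warning.

Transcription-factor sub-shortlisting intersects the shortlist with a
user-supplied annotation set; probeset→gene collapsing keeps a gene if
any of its probesets passes. Neither the annotation source nor the
collapsing map is part of the package.

## Behavioral rhythms

The chi-squared periodogram folds the record into K complete cycles of
each whole-bin trial period P and computes Q_P = K·Σ_h(M_h − M)²/s²,
where s² is the total (population-form) variance of the folded samples;
trailing partial cycles are dropped, which keeps the χ²(P−1) null exact
for iid counts. The best period maximizes the excess of Q_P over its
χ² critical value (α = 0.05 default). With 5-min bins the period grid
has 1/12-h resolution, so a 23.6-h free run is recoverable to
within 0.02 h.

Onset detection is a documented heuristic (the historical analyses used
closed commercial software): smooth with a centered 30-min moving
average, find the first run per calendar day where the smoothed rate
exceeds 0.2× that day's smoothed maximum after ≥4 h of sub-threshold
activity, then refine to the first raw bin at threshold near the
crossing. Days with no qualifying crossing yield explicit gap records.
The linear drift (h/day) is fitted on phase-unwrapped onsets.

Days-to-re-entrain: the pre-shift steady state is the circular mean
onset before the shift day; the count is the smallest d ≥ 1 such that
the onsets on days shift+d … shift+d+2 all lie within 0.5 h of the
shifted target (tolerance and run length configurable). The shift sign
convention is the signed change of onset time: an 8-h advance of the
light schedule is −8 h. Because the underlying criterion used for the
published day counts was never specified, those counts are not exactly
recoverable even in principle; the defaults here are stated so results
are reproducible within this package.

## MUA phase synchrony

Channels are min-max normalized over the recording and mean-binned to
1 h. Quality control mirrors standard electrode practice: flat channels
(range ≤ 1e-10 relative) and monotonically decreasing channels are
excluded with warnings. Per 24-h day, the hourly trace is smoothed with
a centered 3-h moving average (circular within the day; a symmetric
kernel cannot shift the peak of a sinusoid) and fitted with a
fixed-period 24-h sinusoid — a single-day window cannot estimate the
period, so the period is fixed and only the phase is free. Fit quality
is the ratio of fitted amplitude to the residual RMS measured against
the raw (unsmoothed) day — measuring it against the smoothed trace
would let white-noise channels pass — with floor 1.0; below the floor
the record is flagged and excluded from synchrony. At this floor ≈2.5%
of pure-noise channels pass while noiseless sinusoids pass with phase
error < 0.1 h.

Synchrony on a day is the circular resultant length R of the usable
channel phases (R = 1 iff all equal; R = 0 for an antipodal pair or
uniform dispersion), the circular mean phase, and the circular SD
√(−2 ln R)·24/2π hours. R is invariant under common phase rotation.
For wrapped-normal phase dispersion σ (radians) the population value is
R = e^{−σ²/2}, which the desynchronization generator reproduces; the
population-mean rhythm amplitude falls with R at fixed per-channel
amplitude, so "dampening" of the average trace reflects desynchrony,
not silenced oscillators.

## Synthetic data generators

The generators emulate the screening study designs exactly: 24 samples
every 2 h from CT18 (one pooled value per time point, as when several
SCNs are pooled per array); 9 paired light/dark conditions whose dark
values are drawn from the same circadian trajectory as the dark cohort
(not re-drawn baselines); an 83-tissue atlas whose SCN column is the
time-course median and whose replicate pairs differ only by noise;
5-min-bin actograms under LD/DD with free-running, shifting and
re-entraining onset rules; and per-channel sinusoidal MUA with planted
period/phase spreads, daily phase diffusion and scheduled phase
contraction (a phenomenological stand-in for daily neuropeptide
application — no mechanistic coupling model is attempted).

Measurement noise is multiplicative log-normal with unit mean;
intensities stay positive like array data. Defaults: CV 0.15, relative
amplitude 0.5 for planted cyclers, periods uniform in [20, 30] h,
baseline intensities log-normal around 500 (log-SD 0.5) so that typical
medians clear the 100-unit expression filter; planted light effects are
3× induction / 0.25× suppression at three random conditions per gene;
planted enrichment is 10× over background. Relative amplitude must be
< 1 (otherwise the noiseless trough would be non-positive). Identical
seed and design give identical output for every generator, and truth
tables cover every generated probeset/channel exactly once.

What passing the validation suite shows — and does not. The generators
produce stationary, single-harmonic, log-normal data with exactly known
designs. Passing calibration and recovery tests therefore establishes
the statistical machinery (test calibration, estimator accuracy,
threshold semantics, set arithmetic), but not robustness to features of
real SCN data the generators do not emulate: non-sinusoidal waveforms,
damped or drifting rhythms within the record, probe-level saturation,
correlated noise across probesets, or tissue-dependent noise in the
atlas.

## Problem sizes and numerical choices

The validation suite uses the sizes its results are quoted at: 5000
noise series for G-test calibration, 2000 series × 200 permutations for
the permutation test, 200 planted genes for recovery, 20 seeds for
enrichment recall/FDR, 1000 simulations for the periodogram null, 1000
draws for the uniform-R mean. The end-to-end exact-recovery screen runs
noiseless at 200 probesets with permutation count 200 (any B ≥ 20 gives
p = 1/(B+1) < 0.05 for a noiseless cycler) and a baseline log-SD of 0.3
so planted cyclers sit comfortably above the 100-unit median filter.

Numerical notes: the cosinor grid search tracks the running RSS minimum
in tie-preference order (24 h first), so exact ties resolve toward
24 h; degenerate (constant) series report the preferred period with a
degenerate flag. RSS is computed as yᵀy − coefᵀXᵀy and clipped at 0.
Z-score agreement with brute-force arithmetic is asserted with a
combined relative/absolute tolerance of 1e-12 (|Δ|/max(|expected|, 1)):
a Z score is a dimensionless SD count with natural scale 1, and a raw
relative error is ill-conditioned when the SCN value lands on the atlas
mean and z → 0 by cancellation (observed absolute agreement ~1e-14).
Probabilities from the Fisher-G closed form are clipped to [0, 1]
against alternating-series rounding.
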