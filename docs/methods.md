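# Methods

## Scope and data model

`hrvgate` analyzes one participant-night at a time as a pair of beat
series: a *device* series (PPG-derived interbeat intervals, IBIs, each
with an ordinal validity rating 0–4 of which only 1 denotes a valid
reading) and a *reference* series (ECG-style normal-to-normal, NN,
intervals). Both use seconds-from-bed-time as the time axis; intervals
in ms are always consistent with successive beat-time differences to
better than 1 µs. The analysis period is time-in-bed (TIB), bed-time to
wake-time as assessed by the device.

## Quality gating

Device cascade, in order of definition (the final mask is the
conjunction of the stages, so application order is immaterial):

1. **Rating filter** — keep intervals rated 1.
2. **Neighbor rule** — keep an interval only if every existing rating
   within two intervals on either side is also 1. Windows are *clipped*
   at the series ends: an edge interval is judged on the neighbors it
   actually has. The alternative (failing edge intervals outright) was
   rejected because it makes the device chain remove the first and last
   two intervals of every night that the reference chain keeps,
   breaking the exact device/reference equality that must hold when no
   corruption is present.
3. **Plausibility band** — keep 375 ms ≤ IBI ≤ 2000 ms (HR 30–160 bpm
   during sleep). Bounds are inclusive: the removal criteria are strict
   inequalities, so the boundary values themselves are retained.

Reference NN screen: the same plausibility band, plus a maximum relative
change of 30 % between consecutive intervals. The change rule is
forward-only and uses the *raw* preceding interval as denominator
(detection-time semantics); it is not re-applied after gaps are spliced,
where it would not be a fixed point.

## Segmentation and acceptance

TIB is divided into contiguous half-open 5-min windows anchored at
bed-time; a trailing partial window is dropped. An interval belongs to
the window containing its *ending* beat time, so every interval is
atomic: one straddling a boundary contributes its full duration to one
window, and the validity proportion is clamped at 1.

The **duration-based validity proportion** of a window is the clamped
sum of valid IBI durations divided by the window length. A count-based
proportion is deliberately not used for gating: invalid readings can be
unusually long or short (merged or split beats), so the IBI count is not
a reliable indicator of the true number of heartbeats. The synthetic
generator corrupts durations inside artefact episodes precisely so that
the two definitions diverge and the distinction stays regression-tested.

Acceptance rules (all comparisons inclusive):

- device segment: proportion ≥ threshold (default sweep 30/50/80/95 %;
  240 s of valid IBIs passes 80 % exactly);
- device night: ≥ 20 accepted 5-min epochs, evaluated per threshold;
- reference segment: ≥ 150 valid NN intervals (50 % of a 5-min window
  at 60 bpm);
- reference night: ≥ 50 % of grid windows accepted;
- paired segments: the intersection of both chains' accepted windows,
  computed only when both night rules pass.

## Metrics

- **Mean HR** = 60000 / mean(IBI ms): the duration-weighted rate, not
  the mean of per-beat instantaneous rates.
- **rMSSD** uses successive-difference pairs restricted to intervals
  adjacent in the original recording with both members valid; pairs
  never span a gap left by a rejected interval. With no gaps this is
  the textbook rMSSD. A segment with no valid pair has rMSSD undefined
  (NaN) and is excluded from that metric's comparisons.
- **Spectral HRV**: classical Lomb–Scargle periodogram of the
  mean-centred valid intervals sampled at their beat times — no
  interpolation or resampling. Grid: 1/300 Hz to 0.5 Hz with 4-fold
  oversampling of the segment's natural spacing 1/T. The statistic is
  scaled to a one-sided density, 2·τ̄·P(f) with τ̄ the mean sampling
  interval, so that band integration approximates the variance
  contribution; for white input the full-band integral equals the
  sample variance (Parseval), which is how the scaling is tested. For
  strongly irregular sampling a spectral line additionally leaks a
  broadband pedestal (a property of the estimator, not of the scaling);
  beat sampling is regular enough that this is negligible. The
  periodogram is evaluated through a complex-exponential recurrence
  across the linear grid; it agrees with `scipy.signal.lombscargle` to
  ~1e-12 relative and is several times faster over the thousands of
  segments a cohort produces.
- **Band powers** by trapezoidal integration over HF = 0.15–0.40 Hz and
  LF = 0.04–0.15 Hz (the conventional short-term bands);
  **HFnu** = HF / (HF + LF) ∈ [0, 1].
- A segment needs ≥ 30 valid samples for a spectral estimate (≈10 % of
  a 5-min segment at 60 bpm); below that the spectral metrics are
  undefined rather than extrapolated.

**Aggregation.** 30-min windows are non-overlapping bed-time-anchored
blocks of six grid windows; the night is one window. Aggregates are
arithmetic means of the paired 5-min values and are kept only with ≥ 3
(30-min) or ≥ 20 (night) contributing segments; the minima are applied
per metric on the segments where both sources have finite values. HFnu
is normalized per 5-min segment and the normalized values are averaged
(the alternative — averaging HF and LF first, normalizing after — gives
systematically different weights to high-power segments; per-segment
normalization keeps every accepted segment's autonomic balance equally
weighted).

## Agreement

Pooled per group × level × metric × threshold (plus a pooled-over-groups
row): Pearson r; Lin's CCC with population (1/n) moments,
2·cov / (σ²ₓ + σ²ᵧ + (μₓ−μᵧ)²); Bland–Altman bias and 95 % limits of
agreement of d = device − reference, bias ± 1.96·SD(d) with the sample
(n−1) SD. Correlations are pooled over all paired windows within a
group (pooled scatter), not averaged per-participant correlations.

Error metrics MAE, MAPE and MdAPE are computed per participant per
level × metric × threshold, with the reference value as denominator;
MdAPE is the median of absolute percentage errors. Pairs with a zero
reference value are excluded from the percentage metrics with a logged
count. MAPE/MdAPE < 10 % is flagged acceptable. The participant ×
threshold MdAPE heatmap table sorts rows by each participant's mean
MdAPE across thresholds, descending.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable against
known ground truth.

**Reference beats.** Integral-pulse-frequency-modulation style: the
instantaneous interval is
m(t) = base_ibi + lf_amp·sin(2π·0.095·t + φ_LF)
 + hf_amp·sin(2π·0.275·t + φ_HF) + ε, with ε white Gaussian noise
truncated at ±4 SD, and each next beat is placed m(t)/1000 s after the
previous one. Sinusoidal modulation (rather than an AR process) makes
the LF/HF band content — hence HFnu — known by construction, and gives
a closed-form ensemble rMSSD,
√(2·A_L²·sin²(π f_L τ) + 2·A_H²·sin²(π f_H τ) + 2σ²), used as a
parameter-recovery oracle. Parameter sets whose worst-case swing could
leave the 375–2000 ms plausibility band are rejected up front with the
offending parameter named.

**Device corruption.** Every beat time receives i.i.d. Gaussian jitter
(SD `jitter_sd`). Artefact episodes arrive as a Poisson process
(`artefact_rate` per hour) with exponential lengths
(`artefact_mean_len`), forming contiguous bursts rather than i.i.d.
flips — bursts are what make the 2-before/2-after neighbor rule
consequential. Inside an episode each interior beat is deleted
(merging two IBIs) or duplicated by a spurious beat (splitting an IBI,
at 35–65 % of the interval) with probability `corrupt_prob` each, and
every interval touching an episode gets an invalid rating drawn
uniformly from {0, 2, 3, 4} (no public description distinguishes the
non-valid rating classes, so they are treated as one invalid class with
arbitrary labels). With jitter and artefacts disabled the device series
is identical to the reference with all ratings 1 — the end-to-end null
condition under which the full pipeline must report perfect agreement
exactly.

**Cohort structure and defaults.** One global seed; each participant
gets an independent, deterministically spawned substream. Defaults:
7.5 h TIB; 10 younger + 10 older participants. Group presets
(per-participant values drawn around them): younger — mean HR 62 ± 6
bpm, LF/HF modulation 35/40 ms (≈49 ms ensemble rMSSD with 15 ms
beat-to-beat noise), 5 ms jitter, 2.5 artefact episodes/h of mean 75 s;
older — mean HR 58 ± 5 bpm, 20/18 ms modulation (≈26 ms rMSSD with
10 ms noise), 9 ms jitter, 3.5 episodes/h of mean 90 s. These emulate
healthy in-lab sleepers with the older group at lower HR and rMSSD
ranges and noisier device timing; amplitudes get a lognormal
between-participant spread (0.25 log-SD).

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: within-night nonstationarity of
autonomic tone (sleep-stage structure; amplitudes and phases are fixed
per night), ectopic-beat electrophysiology, PPG waveform morphology and
its age-related distortion, and free-living artefact rates. Two
consequences are worth stating explicitly. First, agreement numbers on
synthetic cohorts characterize the pipeline, not any physical device.
Second, because the generator is stationary within a night, the
device−reference difference at aggregated levels is dominated by each
participant's deterministic jitter-induced rMSSD/HFnu inflation, which
averaging cannot reduce: Bland–Altman limits therefore narrow markedly
from 5-min to 30-min aggregation but are statistically indistinguishable
between 30-min and night levels on a 20-participant cohort (the residual
true SD reduction is smaller than the sampling noise of the SD
estimate). On real nights, where true HRV varies with sleep stage,
night-level limits narrow further.

## Numerical and reporting choices

- Cohort-level MdAPE (the median APE over all paired 5-min segments in
  a group) is the summary statistic for threshold comparisons; the
  median across participants of per-participant MdAPEs estimates the
  same effect but is materially noisier at 20 participants and is
  reported in the per-participant tables instead.
- Thresholds are validated to (0, 1], sorted unique; acceptance flags
  are monotone non-increasing in the threshold by construction.
- Metrics are computed once per window per source; thresholds only gate
  which windows enter the paired tables.
- Degenerate inputs are flagged rather than guessed: empty windows give
  NaN metrics, correlations need n ≥ 3 and non-zero variance, CCC needs
  a non-degenerate denominator.
- CSV round-trips are exact (full float precision on write,
  round-trip-precision parsing on read); malformed night files are
  rejected individually with a message while the rest of a cohort is
  still analyzed.

## Problem sizes

Default runs use 20 participants × 7.5 h nights (~28 000 beats per
series, 90 five-min windows per night), which resolves all the
qualitative effects of interest — threshold-dependent retention and
MdAPE, jitter-induced bias, window-size-dependent limits of agreement —
while a full pipeline run completes in well under a minute on one core.
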