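"""HR and HRV metrics per 5-min segment, and 30-min/night aggregation.

Per segment: mean HR (60000 / mean IBI), rMSSD over successive pairs of
intervals that are adjacent in the original recording with both valid,
and Lomb-Scargle band powers of the mean-centred interval series sampled
at its beat times. HF (0.15-0.40 Hz) is normalized against LF
(0.04-0.15 Hz) to HF in normalized units, HFnu = HF / (HF + LF).

The periodogram is evaluated on a grid from 1/300 Hz to 0.5 Hz with
4-fold oversampling of the segment's natural frequency spacing, and
scaled to a one-sided density (ms^2/Hz) such that band integration
approximates the variance contribution: for the unnormalized
Lomb-Scargle statistic P, density = 2 * tau * P with tau the mean
sampling interval, which makes the integral over the full band equal the
sample variance for white input (Parseval property).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

HF_BAND = (0.15, 0.40)
LF_BAND = (0.04, 0.15)
FREQ_MIN = 1.0 / 300.0
FREQ_MAX = 0.5
LS_OVERSAMPLE = 4
MIN_SPECTRAL_SAMPLES = 30
AGG_MIN_SEGMENTS = {"30min": 3, "night": 20}
SEGMENTS_PER_30MIN = 6


@dataclass
class Spectrum:
    """One-sided power spectral density of an interval series.

    frequencies in Hz (strictly increasing), power in ms^2/Hz.
    """

    frequencies: np.ndarray
    power: np.ndarray


def mean_hr(intervals_ms: np.ndarray) -> float:
    """Mean heart rate in bpm: 60000 / mean(IBI in ms)."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if intervals_ms.size == 0:
        raise ValueError("mean_hr needs at least one interval")
    return 60000.0 / float(np.mean(intervals_ms))


def rmssd(intervals_ms: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Root mean square of successive differences, in ms.

    Positions index the original recording order; a difference pair is
    used only when two consecutive positions are both valid, so pairs
    never span a gap left by a rejected or missing interval. Returns NaN
    when no pair exists (metric undefined for the segment).
    """
    x = np.asarray(intervals_ms, dtype=float)
    if valid is None:
        valid = np.ones(x.size, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        return float("nan")
    d = np.diff(x)[pair]
    return float(np.sqrt(np.mean(d * d)))


def _scargle_power(t: np.ndarray, y: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Classical Scargle least-squares periodogram on a linear frequency
    grid (agrees with ``scipy.signal.lombscargle`` to ~1e-12 relative).

    Evaluated through a complex-exponential recurrence across the grid,
    exp(i w_k t) = exp(i w_0 t) * exp(i dw t)^k, which avoids per-element
    trigonometry and is several times faster than direct evaluation for
    the thousands of 5-min segments a cohort produces.
    """
    w = 2.0 * math.pi * freqs
    n_f, n = freqs.size, t.size
    base = np.empty((n_f, n), dtype=complex)
    base[0] = np.exp(1j * w[0] * t)
    if n_f > 1:
        base[1:] = np.exp(1j * (w[1] - w[0]) * t)
    e = np.cumprod(base, axis=0)  # e[k] = exp(i w_k t)
    s2 = (e * e).sum(axis=1)  # sum of exp(2 i w t), for Scargle's tau
    rot = np.exp(-0.5j * np.arctan2(s2.imag, s2.real))
    er = e * rot[:, None]
    c, s = er.real, er.imag
    yc = c @ y
    ys = s @ y
    cc = (c * c).sum(axis=1)
    return 0.5 * (yc * yc / cc + ys * ys / (n - cc))


def lomb_periodogram(
    beat_times_s: np.ndarray,
    intervals_ms: np.ndarray,
    *,
    fmin: float = FREQ_MIN,
    fmax: float = FREQ_MAX,
    oversample: int = LS_OVERSAMPLE,
    min_samples: int = MIN_SPECTRAL_SAMPLES,
) -> Spectrum:
    """Lomb-Scargle density of the mean-centred intervals at their beat
    times. Raises ``ValueError`` below ``min_samples`` valid samples
    (the segment's spectral metrics are then undefined)."""
    t = np.asarray(beat_times_s, dtype=float)
    x = np.asarray(intervals_ms, dtype=float)
    if t.size != x.size:
        raise ValueError("beat times and intervals must align")
    if t.size < min_samples:
        raise ValueError(
            f"{t.size} valid samples < {min_samples} required for a spectrum"
        )
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("beat times must span a positive duration")
    df = 1.0 / (span * oversample)
    freqs = np.arange(fmin, fmax + df / 2.0, df)
    y = x - x.mean()
    pgram = _scargle_power(t, y, freqs)
    tau = span / (t.size - 1)  # mean sampling interval, s
    return Spectrum(frequencies=freqs, power=2.0 * tau * pgram)


def band_power(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal area of the density over [lo, hi], in ms^2."""
    f = spectrum.frequencies
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError(f"band [{lo}, {hi}] Hz outside spectrum grid")
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(spectrum.power[sel], f[sel]))


def hf_nu(hf: float, lf: float) -> float:
    """HF in normalized units: HF / (HF + LF). NaN when both are zero."""
    if hf < 0 or lf < 0:
        raise ValueError("band powers must be non-negative")
    total = hf + lf
    if total == 0:
        return float("nan")
    return hf / total


@dataclass
class SegmentMetrics:
    hr: float
    rmssd: float
    hf_power: float
    lf_power: float
    hf_nu: float
    n_beats: int
    n_diff_pairs: int


def segment_metrics(
    intervals_ms: np.ndarray,
    end_times_s: np.ndarray,
    valid: np.ndarray,
    *,
    hf_band=HF_BAND,
    lf_band=LF_BAND,
    oversample: int = LS_OVERSAMPLE,
    min_spectral_samples: int = MIN_SPECTRAL_SAMPLES,
) -> SegmentMetrics:
    """All metrics for one window's intervals (a contiguous slice of the
    recording, with the per-interval validity mask). Metrics that cannot
    be computed are NaN."""
    valid = np.asarray(valid, dtype=bool)
    x = np.asarray(intervals_ms, dtype=float)[valid]
    t = np.asarray(end_times_s, dtype=float)[valid]
    n = x.size
    hr = mean_hr(x) if n else float("nan")
    pair = valid[:-1] & valid[1:] if valid.size > 1 else np.zeros(0, dtype=bool)
    n_pairs = int(pair.sum())
    rm = rmssd(intervals_ms, valid) if n_pairs else float("nan")
    hf = lf = nu = float("nan")
    if n >= min_spectral_samples:
        spec = lomb_periodogram(
            t, x, oversample=oversample, min_samples=min_spectral_samples
        )
        hf = band_power(spec, *hf_band)
        lf = band_power(spec, *lf_band)
        nu = hf_nu(hf, lf)
    return SegmentMetrics(
        hr=hr,
        rmssd=rm,
        hf_power=hf,
        lf_power=lf,
        hf_nu=nu,
        n_beats=n,
        n_diff_pairs=n_pairs,
    )


METRIC_COLUMNS = ["hr", "rmssd", "hf_nu"]


def aggregate(
    window_idx: np.ndarray, values: np.ndarray, level: str
) -> dict[int, float]:
    """Average 5-min metric values into 30-min or night windows.

    30-min windows are non-overlapping bed-time-anchored blocks of six
    consecutive grid windows; the night is one window. A window is kept
    only with at least 3 (30-min) or 20 (night) contributing finite
    5-min values. Returns {aggregate window index: mean}.
    """
    if level not in AGG_MIN_SEGMENTS:
        raise ValueError(f"unknown aggregation level {level!r}")
    window_idx = np.asarray(window_idx, dtype=int)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    window_idx, values = window_idx[ok], values[ok]
    keys = window_idx // SEGMENTS_PER_30MIN if level == "30min" else np.zeros(
        window_idx.size, dtype=int
    )
    out: dict[int, float] = {}
    min_n = AGG_MIN_SEGMENTS[level]
    for key in np.unique(keys):
        sel = keys == key
        if int(sel.sum()) >= min_n:
            out[int(key)] = float(values[sel].mean())
    return out


def night_metrics_table(
    participant_id: str,
    source: str,
    assignment,
    intervals_ms: np.ndarray,
    end_times_s: np.ndarray,
    valid: np.ndarray,
    grid,
    **kwargs,
) -> pd.DataFrame:
    """5-min metrics for every grid window of one night/source."""
    rows = []
    for w in range(grid.n_windows):
        sl = assignment.window_slice(w)
        m = segment_metrics(
            intervals_ms[sl], end_times_s[sl], valid[sl], **kwargs
        )
        rows.append(
            {
                "participant_id": participant_id,
                "source": source,
                "window_idx": w,
                "hr": m.hr,
                "rmssd": m.rmssd,
                "hf_ms2": m.hf_power,
                "lf_ms2": m.lf_power,
                "hf_nu": m.hf_nu,
                "n_beats": m.n_beats,
                "n_diff_pairs": m.n_diff_pairs,
            }
        )
    return pd.DataFrame(rows)
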