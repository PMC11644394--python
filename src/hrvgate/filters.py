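"""Per-interval validity cascade for device IBIs and reference NN screen.

Device cascade (in order): rating filter (only rating 1 is valid), a
neighbor rule (an interval is kept only if the ratings of up to two
immediately preceding and succeeding intervals are also 1), and a
physiological plausibility band for sleep (375-2000 ms, i.e. 30-160 bpm,
bounds inclusive). The final mask is the conjunction of the stages, so
the cascade is order-independent.

Reference NN screen: the same plausibility band plus a maximum relative
change of 30 % between consecutive intervals (forward-only, against the
raw preceding interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import DEVICE, REFERENCE, BeatSeries

PLAUSIBLE_LOW_MS = 375.0
PLAUSIBLE_HIGH_MS = 2000.0
NEIGHBOR_SPAN = 2
MAX_REL_CHANGE = 0.30


@dataclass
class QualityMask:
    """Stage-by-stage validity of each device interval."""

    rating_ok: np.ndarray
    neighbor_ok: np.ndarray
    plausible_ok: np.ndarray

    @property
    def final_ok(self) -> np.ndarray:
        return self.rating_ok & self.neighbor_ok & self.plausible_ok

    def stage_counts(self) -> dict[str, int]:
        return {
            "n_intervals": int(self.rating_ok.size),
            "rating_ok": int(self.rating_ok.sum()),
            "neighbor_ok": int((self.rating_ok & self.neighbor_ok).sum()),
            "final_ok": int(self.final_ok.sum()),
        }


@dataclass
class ReferenceMask:
    """Validity of each reference NN interval."""

    bounds_ok: np.ndarray
    delta_ok: np.ndarray

    @property
    def final_ok(self) -> np.ndarray:
        return self.bounds_ok & self.delta_ok


def filter_ratings(series: BeatSeries) -> np.ndarray:
    """rating_ok: the device's ordinal rating equals 1."""
    if series.ratings is None:
        raise ValueError("rating filter needs a device series with ratings")
    return series.ratings == 1


def filter_neighbors(rating_ok: np.ndarray, span: int = NEIGHBOR_SPAN) -> np.ndarray:
    """neighbor_ok: all existing ratings within ``span`` on both sides are
    valid (windows are clipped at the series ends, so edge intervals are
    judged on the neighbors they actually have)."""
    rating_ok = np.asarray(rating_ok, dtype=bool)
    n = rating_ok.size
    bad = (~rating_ok).astype(float)
    kernel = np.ones(2 * span + 1)
    # zero-padded window sums are exactly the clipped-window rule; slicing
    # the full convolution keeps the alignment for series shorter than the
    # kernel, where mode='same' would change the output length
    near_bad = np.convolve(bad, kernel, mode="full")[span : span + n]
    return near_bad == 0


def filter_plausible(
    series: BeatSeries,
    low_ms: float = PLAUSIBLE_LOW_MS,
    high_ms: float = PLAUSIBLE_HIGH_MS,
) -> np.ndarray:
    """plausible_ok: interval within the sleep plausibility band, bounds
    inclusive (375 ms and 2000 ms themselves are kept)."""
    return (series.intervals >= low_ms) & (series.intervals <= high_ms)


def device_quality_mask(
    series: BeatSeries,
    *,
    low_ms: float = PLAUSIBLE_LOW_MS,
    high_ms: float = PLAUSIBLE_HIGH_MS,
    span: int = NEIGHBOR_SPAN,
) -> QualityMask:
    """Full device cascade: rating -> neighbor -> plausibility."""
    if series.source != DEVICE:
        raise ValueError("device cascade applies to device series")
    rating_ok = filter_ratings(series)
    return QualityMask(
        rating_ok=rating_ok,
        neighbor_ok=filter_neighbors(rating_ok, span=span),
        plausible_ok=filter_plausible(series, low_ms, high_ms),
    )


def filter_reference_nn(
    series: BeatSeries,
    *,
    low_ms: float = PLAUSIBLE_LOW_MS,
    high_ms: float = PLAUSIBLE_HIGH_MS,
    max_rel_change: float = MAX_REL_CHANGE,
) -> ReferenceMask:
    """Reference NN screen: plausibility bounds plus the 30 % maximum
    consecutive-change rule (first interval: bounds check only)."""
    if series.source != REFERENCE:
        raise ValueError("NN screen applies to reference series")
    nn = series.intervals
    bounds_ok = (nn >= low_ms) & (nn <= high_ms)
    delta_ok = np.ones(nn.size, dtype=bool)
    if nn.size > 1:
        rel = np.abs(np.diff(nn)) / nn[:-1]
        delta_ok[1:] = rel <= max_rel_change
    return ReferenceMask(bounds_ok=bounds_ok, delta_ok=delta_ok)


def valid_mask(series: BeatSeries, **kwargs) -> np.ndarray:
    """final_ok for either source, using that source's own cascade."""
    if series.source == DEVICE:
        return device_quality_mask(series, **kwargs).final_ok
    return filter_reference_nn(series, **kwargs).final_ok
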