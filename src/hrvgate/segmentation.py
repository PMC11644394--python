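"""5-min segment grid over time-in-bed, validity proportions and
segment/night acceptance rules.

The grid is anchored at bed-time with contiguous half-open windows
[start, start + 300); a trailing partial window is dropped. Each
interval belongs to the window containing its *ending* beat time, so an
interval straddling a boundary contributes its full duration to one
window and the per-window validity proportion is clamped at 1.

Device segments are accepted when the duration-based validity
proportion (sum of valid IBI durations / window length) meets the
threshold; a device night must have at least 20 accepted segments.
Reference segments are accepted on a count rule (>= 150 valid NN
intervals); a reference night needs at least 50 % of its segments
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import BeatSeries

WINDOW_LEN_S = 300.0
DEVICE_MIN_EPOCHS = 20
REFERENCE_MIN_NN = 150
REFERENCE_NIGHT_FRACTION = 0.5
DEFAULT_THRESHOLDS = (0.30, 0.50, 0.80, 0.95)


@dataclass(frozen=True)
class SegmentGrid:
    """Non-overlapping contiguous 5-min windows covering [0, TIB)."""

    tib_s: float
    window_len_s: float = WINDOW_LEN_S

    def __post_init__(self) -> None:
        if self.tib_s <= 0 or self.window_len_s <= 0:
            raise ValueError("grid needs positive TIB and window length")

    @property
    def n_windows(self) -> int:
        return int(self.tib_s // self.window_len_s)

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_len_s


def make_grid(tib_s: float, window_len_s: float = WINDOW_LEN_S) -> SegmentGrid:
    return SegmentGrid(tib_s=tib_s, window_len_s=window_len_s)


@dataclass
class Assignment:
    """Window membership of each interval.

    ``window_idx[i]`` is the window containing interval i's ending beat
    time, or -1 if that time falls past the last full window (dropped).
    ``bounds`` gives, for each window w, the contiguous slice
    ``bounds[w]:bounds[w + 1]`` of interval indices it holds.
    """

    window_idx: np.ndarray
    bounds: np.ndarray
    n_dropped: int

    def window_slice(self, w: int) -> slice:
        return slice(int(self.bounds[w]), int(self.bounds[w + 1]))


def assign_intervals(series: BeatSeries, grid: SegmentGrid) -> Assignment:
    """Assign every interval to the window of its ending beat time."""
    end_times = series.interval_end_times
    raw = np.floor(end_times / grid.window_len_s).astype(int)
    n_win = grid.n_windows
    window_idx = np.where(raw < n_win, raw, -1)
    # end times are increasing, so window membership is a sorted run
    bounds = np.searchsorted(raw, np.arange(n_win + 1))
    n_dropped = int(end_times.size - bounds[-1])
    return Assignment(window_idx=window_idx, bounds=bounds, n_dropped=n_dropped)


def validity_proportion(
    series: BeatSeries,
    assignment: Assignment,
    valid: np.ndarray,
    grid: SegmentGrid,
) -> np.ndarray:
    """Duration-based validity proportion per window:
    clamp(sum of valid IBI durations, 0, window) / window."""
    ok = (assignment.window_idx >= 0) & valid
    dur_s = np.bincount(
        assignment.window_idx[ok],
        weights=series.intervals[ok] / 1000.0,
        minlength=grid.n_windows,
    )
    return np.minimum(dur_s, grid.window_len_s) / grid.window_len_s


def valid_counts(
    assignment: Assignment, valid: np.ndarray, grid: SegmentGrid
) -> np.ndarray:
    """Number of valid intervals per window."""
    ok = (assignment.window_idx >= 0) & valid
    return np.bincount(assignment.window_idx[ok], minlength=grid.n_windows).astype(int)


def accept_device_segment(proportion, threshold: float):
    """Device segment passes when its validity proportion >= threshold
    (inclusive: 240 s of valid IBIs passes the 80 % threshold exactly)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return np.asarray(proportion) >= threshold


def accept_reference_segment(
    counts: np.ndarray, min_nn: int = REFERENCE_MIN_NN
) -> np.ndarray:
    """Reference segment passes with at least ``min_nn`` valid NN intervals."""
    return np.asarray(counts) >= min_nn


def accept_night(accepted: np.ndarray, source: str, n_windows: int | None = None) -> bool:
    """Night-level coverage rule.

    Device nights need at least 20 accepted 5-min epochs; reference
    nights need at least 50 % of the grid's windows accepted.
    """
    accepted = np.asarray(accepted, dtype=bool)
    if source == "device":
        return int(accepted.sum()) >= DEVICE_MIN_EPOCHS
    if source == "reference":
        n = accepted.size if n_windows is None else n_windows
        if n == 0:
            return False
        return accepted.sum() >= REFERENCE_NIGHT_FRACTION * n
    raise ValueError(f"unknown source {source!r}")


def pair_segments(device_accepted: np.ndarray, reference_accepted: np.ndarray) -> np.ndarray:
    """Window indices accepted by both quality-control chains."""
    both = np.asarray(device_accepted, dtype=bool) & np.asarray(
        reference_accepted, dtype=bool
    )
    return np.nonzero(both)[0]


def retention_rate(accepted: np.ndarray) -> float:
    """Percentage of windows retained (100 * accepted / initial)."""
    accepted = np.asarray(accepted, dtype=bool)
    if accepted.size == 0:
        return float("nan")
    return 100.0 * accepted.sum() / accepted.size


def segment_table(
    series: BeatSeries,
    assignment: Assignment,
    valid: np.ndarray,
    grid: SegmentGrid,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-window validity summary for one night/source, with acceptance
    flags per device threshold (reference acceptance uses the count rule
    and is reported in every threshold column for symmetry)."""
    prop = validity_proportion(series, assignment, valid, grid)
    counts = valid_counts(assignment, valid, grid)
    dur_s = prop * grid.window_len_s
    df = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "source": series.source,
            "window_idx": np.arange(grid.n_windows),
            "window_start_s": grid.window_starts,
            "n_valid": counts,
            "valid_duration_s": dur_s,
            "validity_proportion": prop,
        }
    )
    for thr in thresholds:
        col = f"accepted_{int(round(thr * 100))}"
        if series.source == "device":
            df[col] = accept_device_segment(prop, thr)
        else:
            df[col] = accept_reference_segment(counts)
    return df
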