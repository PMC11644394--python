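"""Beat-interval time series container and its CSV dialect.

A :class:`BeatSeries` holds one participant-night of heartbeats from a
single source: either the wearable ("device", PPG-derived interbeat
intervals with a per-interval validity rating 0-4) or the reference
("reference", ECG-style normal-to-normal intervals, no ratings).
Beat times are seconds from bed-time; intervals are milliseconds and are
always consistent with successive beat-time differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEVICE = "device"
REFERENCE = "reference"

#: maximum tolerated discrepancy between an interval and the difference of
#: its bounding beat times, in ms (1 microsecond)
_CONSISTENCY_TOL_MS = 1e-3


@dataclass
class BeatSeries:
    """One night of beats from one source.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant-night.
    source : {"device", "reference"}
        Which instrument produced the series.
    beat_times : ndarray of float
        Beat timestamps in seconds from bed-time, strictly increasing,
        all within ``[0, tib_s]``.
    intervals : ndarray of float
        Interbeat intervals in ms; ``intervals[i]`` ends at
        ``beat_times[i + 1]``.
    tib_s : float
        Time-in-bed (bed-time to wake-time) in seconds.
    ratings : ndarray of int, optional
        Per-interval validity rating on the device's 0-4 ordinal scale;
        required for device series, absent for reference series.
        Only rating 1 denotes a valid reading.
    bed_time, wake_time : str, optional
        Clock times ("HH:MM"), carried for reporting only; the analysis
        time axis is seconds from bed-time.
    """

    participant_id: str
    source: str
    beat_times: np.ndarray
    intervals: np.ndarray
    tib_s: float
    ratings: np.ndarray | None = None
    bed_time: str | None = None
    wake_time: str | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.ratings is not None:
            self.ratings = np.asarray(self.ratings, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.source not in (DEVICE, REFERENCE):
            raise ValueError(f"unknown source {self.source!r}")
        if self.tib_s <= 0:
            raise ValueError("tib_s must be positive")
        t = self.beat_times
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least two beats")
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if t[0] < 0 or t[-1] > self.tib_s + 1e-9:
            raise ValueError("beat_times must lie within [0, tib_s]")
        if self.intervals.shape != (t.size - 1,):
            raise ValueError("intervals must have len(beat_times) - 1 entries")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")
        err = np.max(np.abs(self.intervals - np.diff(t) * 1000.0))
        if err > _CONSISTENCY_TOL_MS:
            raise ValueError(
                f"intervals disagree with beat-time differences by {err:.3g} ms"
            )
        if self.source == DEVICE:
            if self.ratings is None:
                raise ValueError("device series requires per-interval ratings")
            if self.ratings.shape != self.intervals.shape:
                raise ValueError("ratings must align 1:1 with intervals")
            if self.ratings.min() < 0 or self.ratings.max() > 4:
                raise ValueError("ratings must be on the 0-4 scale")
        elif self.ratings is not None:
            raise ValueError("reference series must not carry ratings")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def n_intervals(self) -> int:
        return self.intervals.size

    @property
    def interval_end_times(self) -> np.ndarray:
        """Time (s from bed-time) of the beat that ends each interval."""
        return self.beat_times[1:]

    @classmethod
    def from_beat_times(
        cls,
        beat_times: np.ndarray,
        *,
        participant_id: str,
        source: str,
        tib_s: float,
        ratings: np.ndarray | None = None,
        bed_time: str | None = None,
        wake_time: str | None = None,
    ) -> "BeatSeries":
        """Build a series with intervals derived from the beat times."""
        beat_times = np.asarray(beat_times, dtype=float)
        return cls(
            participant_id=participant_id,
            source=source,
            beat_times=beat_times,
            intervals=np.diff(beat_times) * 1000.0,
            tib_s=tib_s,
            ratings=ratings,
            bed_time=bed_time,
            wake_time=wake_time,
        )


CSV_COLUMNS = ["beat_time_s", "ibi_ms", "rating"]


def write_beat_series(series: BeatSeries, path: str | Path) -> None:
    """Write one night to CSV (columns ``beat_time_s,ibi_ms,rating``).

    One row per beat; the first beat has no preceding interval so its
    ``ibi_ms``/``rating`` cells are empty, and the ``rating`` column is
    empty throughout for reference series. Full float precision is kept
    so a round-trip reproduces the series exactly.
    """
    n = series.n_beats
    ibi = np.full(n, np.nan)
    ibi[1:] = series.intervals
    rating = np.full(n, np.nan)
    if series.ratings is not None:
        rating[1:] = series.ratings
    df = pd.DataFrame(
        {"beat_time_s": series.beat_times, "ibi_ms": ibi, "rating": rating}
    )
    df["rating"] = df["rating"].astype("Int64")
    df.to_csv(path, index=False)


def read_beat_series(
    path: str | Path,
    *,
    participant_id: str | None = None,
    tib_s: float | None = None,
    bed_time: str | None = None,
    wake_time: str | None = None,
) -> BeatSeries:
    """Read a night CSV written by :func:`write_beat_series`.

    The source is inferred from the rating column: any non-empty rating
    makes it a device series. Raises ``ValueError`` on a malformed file
    (wrong header, non-monotone beat times, inconsistent intervals).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != CSV_COLUMNS:
        raise ValueError(
            f"{path.name}: expected header {','.join(CSV_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    beat_times = df["beat_time_s"].to_numpy(dtype=float)
    has_ratings = df["rating"].notna().to_numpy()
    if has_ratings[1:].all() and len(df) > 1:
        source = DEVICE
        ratings = df["rating"].to_numpy(dtype=float)[1:].astype(int)
    elif not has_ratings.any():
        source = REFERENCE
        ratings = None
    else:
        raise ValueError(f"{path.name}: ratings must be all present or all absent")
    if tib_s is None:
        tib_s = float(beat_times[-1]) if beat_times.size else 0.0
    return BeatSeries(
        participant_id=participant_id or path.stem,
        source=source,
        beat_times=beat_times,
        intervals=df["ibi_ms"].to_numpy(dtype=float)[1:],
        tib_s=tib_s,
        ratings=ratings,
        bed_time=bed_time,
        wake_time=wake_time,
    )


@dataclass
class PairedNight:
    """Device and reference recordings of the same participant-night."""

    participant_id: str
    group: str
    reference: BeatSeries
    device: BeatSeries

    def __post_init__(self) -> None:
        if self.reference.source != REFERENCE or self.device.source != DEVICE:
            raise ValueError("paired night needs one reference and one device series")


def write_cohort(nights: list[PairedNight], out_dir: str | Path) -> Path:
    """Write per-night CSVs plus a manifest JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for night in nights:
        ref_path = out_dir / f"{night.participant_id}_reference.csv"
        dev_path = out_dir / f"{night.participant_id}_device.csv"
        write_beat_series(night.reference, ref_path)
        write_beat_series(night.device, dev_path)
        entries.append(
            {
                "participant_id": night.participant_id,
                "group": night.group,
                "bed_time": night.device.bed_time,
                "wake_time": night.device.wake_time,
                "tib_s": night.device.tib_s,
                "reference_csv": ref_path.name,
                "device_csv": dev_path.name,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"nights": entries}, indent=2))
    return manifest


def read_cohort(
    manifest_path: str | Path, *, collect_errors: bool = False
) -> list[PairedNight] | tuple[list[PairedNight], list[str]]:
    """Load a cohort from a manifest written by :func:`write_cohort`.

    With ``collect_errors=True``, malformed nights are skipped and
    returned as messages alongside the loadable ones instead of raising.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    meta = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    nights = []
    errors: list[str] = []
    for entry in meta["nights"]:
        common = dict(
            participant_id=entry["participant_id"],
            tib_s=entry["tib_s"],
            bed_time=entry.get("bed_time"),
            wake_time=entry.get("wake_time"),
        )
        try:
            nights.append(
                PairedNight(
                    participant_id=entry["participant_id"],
                    group=entry["group"],
                    reference=read_beat_series(
                        base / entry["reference_csv"], **common
                    ),
                    device=read_beat_series(base / entry["device_csv"], **common),
                )
            )
        except ValueError as exc:
            if not collect_errors:
                raise
            errors.append(f"{entry['participant_id']}: {exc}")
    if collect_errors:
        return nights, errors
    return nights
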