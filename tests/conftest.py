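"""Shared fixtures: small hand-built series and session-scoped cohort runs."""

import numpy as np
import pytest

import hrvgate as hg


def make_device_series(intervals_ms, ratings=None, tib_s=None, start_s=0.5, pid="X01"):
    """Device series with beat times laid end-to-end from the intervals."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    beat_times = start_s + np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    if ratings is None:
        ratings = np.ones(intervals_ms.size, dtype=int)
    if tib_s is None:
        tib_s = float(beat_times[-1]) + 1.0
    return hg.BeatSeries(
        participant_id=pid,
        source="device",
        beat_times=beat_times,
        intervals=intervals_ms,
        tib_s=tib_s,
        ratings=np.asarray(ratings, dtype=int),
    )


def make_reference_series(intervals_ms, tib_s=None, start_s=0.5, pid="X01"):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    beat_times = start_s + np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    if tib_s is None:
        tib_s = float(beat_times[-1]) + 1.0
    return hg.BeatSeries(
        participant_id=pid,
        source="reference",
        beat_times=beat_times,
        intervals=intervals_ms,
        tib_s=tib_s,
    )


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on the default 20-participant cohort with all device
    corruption disabled (exact device == reference condition)."""
    cfg = hg.RunConfig(sim=hg.null_config(hg.SimConfig()))
    return hg.run(cfg)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default jittered/artefact 20-participant cohort."""
    return hg.run(hg.RunConfig(sim=hg.SimConfig()))


@pytest.fixture(scope="session")
def small_cohort():
    """Three paired nights under default corruption (for structural tests)."""
    return hg.generate_cohort(hg.SimConfig(n_younger=2, n_older=1, seed=11))
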