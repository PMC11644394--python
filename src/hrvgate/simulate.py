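"""Synthetic paired-cohort generator with known ground-truth HRV.

Reference beat series are produced by an integral-pulse-frequency-
modulation (IPFM) style scheme: the instantaneous interbeat interval is

    m(t) = base_ibi + lf_amp * sin(2*pi*lf_freq*t + phi_LF)
                    + hf_amp * sin(2*pi*hf_freq*t + phi_HF) + noise

and each next beat is placed m(t)/1000 seconds after the previous one.
Because the modulation amplitudes directly set the LF and HF band
content, the spectral ground truth (and hence HF in normalized units)
is known by construction.

Device series are derived from the reference by timing jitter on every
beat plus clustered artefact episodes (a two-state clean/artefact
process) inside which beats may be dropped (merged intervals) or
spuriously inserted (split intervals) and all affected intervals
receive an invalid validity rating drawn from {0, 2, 3, 4}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .series import DEVICE, REFERENCE, BeatSeries, PairedNight

YOUNGER = "younger"
OLDER = "older"

#: white IBI noise is truncated at this many standard deviations so that
#: plausibility of the generated intervals can be guaranteed up front
NOISE_CLIP_SD = 4.0

PLAUSIBLE_LOW_MS = 375.0
PLAUSIBLE_HIGH_MS = 2000.0

_INVALID_RATINGS = np.array([0, 2, 3, 4])


@dataclass(frozen=True)
class GroupPreset:
    """Population parameters for one age group.

    mean_hr / hr_between_sd : bpm
        Cohort mean nocturnal heart rate and its between-participant SD.
    lf_amp, hf_amp : ms
        Sinusoidal IBI modulation amplitudes in the low-frequency and
        high-frequency bands.
    amp_between_sd : log-units
        Between-participant lognormal spread applied to each amplitude.
    noise_sd : ms
        White beat-to-beat IBI noise SD.
    jitter_sd : ms
        Device-side timing noise SD applied to every beat timestamp.
    artefact_rate : episodes per hour
        Expected number of clustered invalid episodes.
    artefact_mean_len : s
        Mean (exponential) artefact episode duration.
    """

    mean_hr: float
    hr_between_sd: float
    lf_amp: float
    hf_amp: float
    amp_between_sd: float
    noise_sd: float
    jitter_sd: float
    artefact_rate: float
    artefact_mean_len: float


def default_presets() -> dict[str, GroupPreset]:
    """Default younger/older presets: healthy in-lab sleepers, with the
    older group at lower HR and rMSSD ranges and noisier device timing."""
    return {
        YOUNGER: GroupPreset(
            mean_hr=62.0,
            hr_between_sd=6.0,
            lf_amp=35.0,
            hf_amp=40.0,
            amp_between_sd=0.25,
            noise_sd=15.0,
            jitter_sd=5.0,
            artefact_rate=2.5,
            artefact_mean_len=75.0,
        ),
        OLDER: GroupPreset(
            mean_hr=58.0,
            hr_between_sd=5.0,
            lf_amp=20.0,
            hf_amp=18.0,
            amp_between_sd=0.25,
            noise_sd=10.0,
            jitter_sd=9.0,
            artefact_rate=3.5,
            artefact_mean_len=90.0,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic paired cohort."""

    n_younger: int = 10
    n_older: int = 10
    tib_hours: float = 7.5
    lf_freq: float = 0.095
    hf_freq: float = 0.275
    presets: Mapping[str, GroupPreset] = field(default_factory=default_presets)
    #: probability that a beat inside an artefact episode is deleted
    #: (merging two intervals) or duplicated by a spurious beat (splitting
    #: an interval); duration corruption is what makes count-based and
    #: duration-based validity proportions diverge
    corrupt_prob: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_younger < 0 or self.n_older < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.tib_hours <= 0:
            raise ValueError("tib_hours must be positive")
        if not (0.04 <= self.lf_freq < 0.15 <= self.hf_freq <= 0.40):
            raise ValueError(
                "need 0.04 <= lf_freq < 0.15 <= hf_freq <= 0.40 "
                f"(got lf_freq={self.lf_freq}, hf_freq={self.hf_freq})"
            )
        if not 0 <= self.corrupt_prob <= 1:
            raise ValueError("corrupt_prob must be in [0, 1]")
        for name, p in self.presets.items():
            for attr in (
                "lf_amp",
                "hf_amp",
                "noise_sd",
                "jitter_sd",
                "artefact_rate",
                "artefact_mean_len",
                "hr_between_sd",
                "amp_between_sd",
            ):
                if getattr(p, attr) < 0:
                    raise ValueError(f"{name}.{attr} must be non-negative")
            if p.mean_hr <= 0:
                raise ValueError(f"{name}.mean_hr must be positive")

    @property
    def tib_s(self) -> float:
        return self.tib_hours * 3600.0


@dataclass(frozen=True)
class ParticipantParams:
    """One participant's realized generative parameters."""

    base_hr: float
    lf_amp: float
    hf_amp: float
    noise_sd: float

    @property
    def base_ibi_ms(self) -> float:
        return 60000.0 / self.base_hr


def check_plausible_range(params: ParticipantParams) -> None:
    """Reject parameter sets that can drive intervals outside 375-2000 ms."""
    swing = params.lf_amp + params.hf_amp + NOISE_CLIP_SD * params.noise_sd
    base = params.base_ibi_ms
    if base - swing < PLAUSIBLE_LOW_MS:
        raise ValueError(
            f"modulation swing {swing:.0f} ms can push intervals below "
            f"{PLAUSIBLE_LOW_MS:.0f} ms at base IBI {base:.0f} ms "
            "(reduce lf_amp/hf_amp/noise_sd or mean_hr)"
        )
    if base + swing > PLAUSIBLE_HIGH_MS:
        raise ValueError(
            f"modulation swing {swing:.0f} ms can push intervals above "
            f"{PLAUSIBLE_HIGH_MS:.0f} ms at base IBI {base:.0f} ms "
            "(reduce lf_amp/hf_amp/noise_sd or increase mean_hr)"
        )


def draw_participant_params(
    preset: GroupPreset, rng: np.random.Generator
) -> ParticipantParams:
    base_hr = float(
        np.clip(rng.normal(preset.mean_hr, preset.hr_between_sd), 40.0, 95.0)
    )
    lf_amp = preset.lf_amp * math.exp(rng.normal(0.0, preset.amp_between_sd))
    hf_amp = preset.hf_amp * math.exp(rng.normal(0.0, preset.amp_between_sd))
    return ParticipantParams(
        base_hr=base_hr, lf_amp=lf_amp, hf_amp=hf_amp, noise_sd=preset.noise_sd
    )


def expected_rmssd(
    params: ParticipantParams, lf_freq: float, hf_freq: float
) -> float:
    """Closed-form ensemble rMSSD implied by the generative model.

    For a sinusoid of amplitude A sampled at the mean beat spacing tau,
    the phase-averaged mean squared successive difference is
    2 A^2 sin^2(pi f tau); independent white noise adds 2 sigma^2.
    """
    tau = params.base_ibi_ms / 1000.0
    mssd = (
        2.0 * params.lf_amp**2 * math.sin(math.pi * lf_freq * tau) ** 2
        + 2.0 * params.hf_amp**2 * math.sin(math.pi * hf_freq * tau) ** 2
        + 2.0 * params.noise_sd**2
    )
    return math.sqrt(mssd)


def simulate_reference_beats(
    config: SimConfig,
    participant_id: str,
    rng: np.random.Generator,
    *,
    group: str = YOUNGER,
    params: ParticipantParams | None = None,
    bed_time: str | None = None,
    wake_time: str | None = None,
) -> BeatSeries:
    """Generate one night's reference (NN) beat series.

    Beats are laid down sequentially: each interval is the modulation
    function evaluated at the current beat time plus truncated white
    noise, so all intervals stay inside the 375-2000 ms plausibility
    band for any accepted parameter set.
    """
    if params is None:
        params = ParticipantParams(
            base_hr=config.presets[group].mean_hr,
            lf_amp=config.presets[group].lf_amp,
            hf_amp=config.presets[group].hf_amp,
            noise_sd=config.presets[group].noise_sd,
        )
    check_plausible_range(params)

    tib_s = config.tib_s
    base = params.base_ibi_ms
    w_l = 2.0 * math.pi * config.lf_freq
    w_h = 2.0 * math.pi * config.hf_freq
    phi_l, phi_h = rng.uniform(0.0, 2.0 * math.pi, size=2)

    # first beat lands a random fraction of one interval after bed-time
    t = float(rng.uniform(0.0, base / 1000.0))
    times = [t]
    sin = math.sin
    noise_buf: np.ndarray = np.empty(0)
    pos = 0
    while True:
        if pos >= noise_buf.size:
            noise_buf = np.clip(
                rng.standard_normal(8192), -NOISE_CLIP_SD, NOISE_CLIP_SD
            ) * params.noise_sd
            pos = 0
        m = (
            base
            + params.lf_amp * sin(w_l * t + phi_l)
            + params.hf_amp * sin(w_h * t + phi_h)
            + noise_buf[pos]
        )
        pos += 1
        t_next = t + m / 1000.0
        if t_next > tib_s:
            break
        times.append(t_next)
        t = t_next

    return BeatSeries.from_beat_times(
        np.asarray(times),
        participant_id=participant_id,
        source=REFERENCE,
        tib_s=tib_s,
        bed_time=bed_time,
        wake_time=wake_time,
    )


def _merge_episodes(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Merge overlapping [start, end) episodes; returns (k, 2) array."""
    if starts.size == 0:
        return np.empty((0, 2))
    order = np.argsort(starts)
    merged = [[starts[order[0]], ends[order[0]]]]
    for i in order[1:]:
        if starts[i] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], ends[i])
        else:
            merged.append([starts[i], ends[i]])
    return np.asarray(merged)


def _in_episode(t: np.ndarray, episodes: np.ndarray) -> np.ndarray:
    if episodes.size == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(episodes[:, 0], t, side="right") - 1
    ok = idx >= 0
    out = np.zeros(t.shape, dtype=bool)
    out[ok] = t[ok] < episodes[idx[ok], 1]
    return out


def corrupt_to_device(
    reference: BeatSeries,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    group: str = YOUNGER,
) -> BeatSeries:
    """Degrade a reference series into the paired device series.

    Timing jitter perturbs every beat; artefact episodes drawn from a
    Poisson process (rate ``artefact_rate``/h, exponential lengths)
    delete or insert beats and flag all intervals they touch with an
    invalid rating. With ``jitter_sd = 0`` and ``artefact_rate = 0``
    the device series is identical to the reference with all ratings 1.
    """
    if reference.source != REFERENCE:
        raise ValueError("corrupt_to_device expects a reference series")
    preset = config.presets[group]
    tib_s = reference.tib_s
    times = reference.beat_times.copy()

    n_ep = rng.poisson(preset.artefact_rate * tib_s / 3600.0)
    ep_starts = rng.uniform(0.0, tib_s, size=n_ep)
    ep_lens = rng.exponential(preset.artefact_mean_len, size=n_ep) if n_ep else np.empty(0)
    episodes = _merge_episodes(ep_starts, ep_starts + ep_lens)

    # duration corruption inside episodes: delete beats (merged IBIs) or
    # insert spurious beats (split IBIs); series endpoints are kept
    keep = np.ones(times.size, dtype=bool)
    inserts: list[float] = []
    interior = np.arange(1, times.size - 1)
    hit = interior[_in_episode(times[interior], episodes)]
    if hit.size:
        u = rng.uniform(size=hit.size)
        delete = u < config.corrupt_prob
        split = (u >= config.corrupt_prob) & (u < 2.0 * config.corrupt_prob)
        keep[hit[delete]] = False
        for i in hit[split]:
            frac = rng.uniform(0.35, 0.65)
            inserts.append(times[i - 1] + frac * (times[i] - times[i - 1]))

    new_times = np.concatenate([times[keep], np.asarray(inserts)])
    if preset.jitter_sd > 0:
        new_times = new_times + rng.normal(
            0.0, preset.jitter_sd / 1000.0, size=new_times.size
        )
    new_times = np.sort(new_times)
    new_times = new_times[(new_times >= 0.0) & (new_times <= tib_s)]
    # collapse numerically coincident beats (possible only under jitter)
    dup = np.diff(new_times) <= 1e-9
    if dup.any():
        new_times = np.delete(new_times, np.nonzero(dup)[0] + 1)

    ratings = np.ones(new_times.size - 1, dtype=int)
    bad = _in_episode(new_times[:-1], episodes) | _in_episode(new_times[1:], episodes)
    n_bad = int(bad.sum())
    if n_bad:
        ratings[bad] = rng.choice(_INVALID_RATINGS, size=n_bad)

    return BeatSeries.from_beat_times(
        new_times,
        participant_id=reference.participant_id,
        source=DEVICE,
        tib_s=tib_s,
        ratings=ratings,
        bed_time=reference.bed_time,
        wake_time=reference.wake_time,
    )


_NOMINAL_BED_MIN = {YOUNGER: 45, OLDER: -5}  # minutes past midnight


def _clock(minutes: float) -> str:
    m = int(round(minutes)) % (24 * 60)
    return f"{m // 60:02d}:{m % 60:02d}"


def generate_cohort(config: SimConfig) -> list[PairedNight]:
    """Generate the full paired cohort, deterministic under the seed.

    Each participant gets an independent substream spawned from the
    single global seed, so nights are reproducible individually and
    jointly.
    """
    groups = [YOUNGER] * config.n_younger + [OLDER] * config.n_older
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(groups))
    nights = []
    counters = {YOUNGER: 0, OLDER: 0}
    for group, child in zip(groups, children):
        counters[group] += 1
        pid = f"{'Y' if group == YOUNGER else 'O'}{counters[group]:02d}"
        rng = np.random.default_rng(child)
        params = draw_participant_params(config.presets[group], rng)
        bed_min = _NOMINAL_BED_MIN[group] + rng.uniform(-45.0, 45.0)
        bed_time = _clock(bed_min)
        wake_time = _clock(bed_min + config.tib_hours * 60.0)
        reference = simulate_reference_beats(
            config,
            pid,
            rng,
            group=group,
            params=params,
            bed_time=bed_time,
            wake_time=wake_time,
        )
        device = corrupt_to_device(reference, config, rng, group=group)
        nights.append(
            PairedNight(
                participant_id=pid, group=group, reference=reference, device=device
            )
        )
    return nights


def null_config(config: SimConfig | None = None, **kwargs) -> SimConfig:
    """A copy of ``config`` with all device corruption disabled
    (zero jitter, zero artefact rate): the end-to-end null condition."""
    config = config or SimConfig(**kwargs)
    presets = {
        name: replace(p, jitter_sd=0.0, artefact_rate=0.0)
        for name, p in config.presets.items()
    }
    return replace(config, presets=presets)
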