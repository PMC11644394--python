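"""Synthetic paired-cohort generator: limits, determinism, ground truth."""

import math

import numpy as np
import pytest

import hrvgate as hg
from hrvgate import metrics, simulate


def _rng(seed=0):
    return np.random.default_rng(seed)


def flat_params(base_hr=60.0, lf=0.0, hf=0.0, noise=0.0):
    return simulate.ParticipantParams(
        base_hr=base_hr, lf_amp=lf, hf_amp=hf, noise_sd=noise
    )


class TestReferenceGeneration:
    def test_constant_rate_limit(self):
        """No modulation, no noise: every interval is exactly the base IBI."""
        cfg = hg.SimConfig(tib_hours=1.0)
        ref = simulate.simulate_reference_beats(
            cfg, "P", _rng(1), params=flat_params()
        )
        assert np.allclose(ref.intervals, 1000.0, atol=1e-9)
        assert hg.mean_hr(ref.intervals) == pytest.approx(60.0)

    def test_deterministic_under_seed(self):
        cfg = hg.SimConfig(tib_hours=1.0)
        p = flat_params(62.0, 30.0, 35.0, 12.0)
        a = simulate.simulate_reference_beats(cfg, "P", _rng(42), params=p)
        b = simulate.simulate_reference_beats(cfg, "P", _rng(42), params=p)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)

    def test_intervals_match_beat_time_differences(self):
        cfg = hg.SimConfig(tib_hours=1.0)
        ref = simulate.simulate_reference_beats(
            cfg, "P", _rng(2), params=flat_params(60.0, 30.0, 40.0, 10.0)
        )
        err_ms = np.abs(ref.intervals - np.diff(ref.beat_times) * 1000.0)
        assert err_ms.max() < 1e-3  # < 1 microsecond

    def test_hf_only_series_peaks_at_hf_freq(self):
        """Spectral oracle: with only HF modulation, the Lomb-Scargle
        periodogram of the generated intervals peaks at hf_freq."""
        cfg = hg.SimConfig(tib_hours=0.5, hf_freq=0.275)
        ref = simulate.simulate_reference_beats(
            cfg, "P", _rng(3), params=flat_params(60.0, 0.0, 40.0, 0.0)
        )
        spec = hg.lomb_periodogram(ref.interval_end_times, ref.intervals)
        f_peak = spec.frequencies[np.argmax(spec.power)]
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(f_peak - cfg.hf_freq) <= df

    def test_rejects_implausible_amplitudes(self):
        cfg = hg.SimConfig(tib_hours=1.0)
        with pytest.raises(ValueError, match="below"):
            simulate.simulate_reference_beats(
                cfg, "P", _rng(0), params=flat_params(90.0, 300.0, 300.0, 0.0)
            )
        with pytest.raises(ValueError, match="above"):
            simulate.simulate_reference_beats(
                cfg, "P", _rng(0), params=flat_params(40.0, 300.0, 300.0, 0.0)
            )

    def test_ensemble_rmssd_matches_closed_form(self):
        """The mean simulated rMSSD converges to the closed form implied by
        the modulation amplitudes and noise SD. The closed form itself is
        cross-checked by a brute-force oracle: sinusoid values sampled at
        the mean beat spacing plus white noise."""
        cfg = hg.SimConfig(tib_hours=2.0)
        p = flat_params(60.0, 35.0, 40.0, 15.0)
        expected = simulate.expected_rmssd(p, cfg.lf_freq, cfg.hf_freq)

        # brute-force oracle: direct sampling of the generative signal
        rng = _rng(99)
        tau = p.base_ibi_ms / 1000.0
        t = np.arange(200_000) * tau
        x = (
            p.lf_amp * np.sin(2 * math.pi * cfg.lf_freq * t + 1.0)
            + p.hf_amp * np.sin(2 * math.pi * cfg.hf_freq * t + 2.5)
            + rng.normal(0, p.noise_sd, t.size)
        )
        brute = float(np.sqrt(np.mean(np.diff(x) ** 2)))
        assert brute == pytest.approx(expected, rel=0.02)

        sims = [
            hg.rmssd(
                simulate.simulate_reference_beats(
                    cfg, "P", _rng(1000 + k), params=p
                ).intervals
            )
            for k in range(4)
        ]
        assert np.mean(sims) == pytest.approx(expected, rel=0.05)


class TestDeviceCorruption:
    def test_no_corruption_is_identity_with_all_ratings_one(self):
        cfg = hg.null_config(hg.SimConfig(tib_hours=1.0))
        ref = simulate.simulate_reference_beats(
            cfg, "P", _rng(5), params=flat_params(62.0, 30.0, 35.0, 12.0)
        )
        dev = simulate.corrupt_to_device(ref, cfg, _rng(6))
        np.testing.assert_array_equal(dev.beat_times, ref.beat_times)
        np.testing.assert_array_equal(dev.intervals, ref.intervals)
        assert (dev.ratings == 1).all()

    def test_valid_fraction_decreases_with_artefact_rate(self):
        """Monte-Carlo over seeds: the per-night fraction of rating-1
        intervals decreases monotonically with the artefact rate."""
        base = hg.SimConfig(tib_hours=2.0)
        fractions = []
        for rate in (0.5, 3.0, 10.0):
            presets = {
                name: simulate.GroupPreset(
                    **{**p.__dict__, "artefact_rate": rate}
                )
                for name, p in base.presets.items()
            }
            cfg = hg.SimConfig(tib_hours=2.0, presets=presets)
            vals = []
            for k in range(5):
                ref = simulate.simulate_reference_beats(
                    cfg, "P", _rng(50 + k), params=flat_params(62, 30, 35, 12)
                )
                dev = simulate.corrupt_to_device(ref, cfg, _rng(500 + k))
                vals.append((dev.ratings == 1).mean())
            fractions.append(np.mean(vals))
        assert fractions[0] > fractions[1] > fractions[2]

    def test_jitter_inflates_rmssd(self):
        """Variance-inflation oracle: i.i.d. timing jitter with SD sigma
        adds 6*sigma^2 to the mean squared successive difference, so the
        device rMSSD exceeds the reference rMSSD on clean segments."""
        jitter = 10.0
        presets = {
            name: simulate.GroupPreset(
                **{**p.__dict__, "jitter_sd": jitter, "artefact_rate": 0.0}
            )
            for name, p in hg.SimConfig().presets.items()
        }
        cfg = hg.SimConfig(tib_hours=3.0, presets=presets)
        p = flat_params(60.0, 35.0, 40.0, 15.0)
        ref = simulate.simulate_reference_beats(cfg, "P", _rng(7), params=p)
        dev = simulate.corrupt_to_device(ref, cfg, _rng(8))
        mssd_ref = np.mean(np.diff(ref.intervals) ** 2)
        mssd_dev = np.mean(np.diff(dev.intervals) ** 2)
        assert hg.rmssd(dev.intervals) > hg.rmssd(ref.intervals)
        assert mssd_dev - mssd_ref == pytest.approx(6 * jitter**2, rel=0.25)

    def test_corrupted_durations_make_count_and_duration_validity_diverge(self):
        """Merged/split beats inside artefact episodes mean the IBI count
        no longer tracks true heartbeats, so count-based and duration-based
        validity proportions must disagree on corrupted nights."""
        cfg = hg.SimConfig(tib_hours=2.0, corrupt_prob=0.5)
        ref = simulate.simulate_reference_beats(
            cfg, "P", _rng(9), params=flat_params(62, 30, 35, 12)
        )
        dev = simulate.corrupt_to_device(ref, cfg, _rng(10), group="older")
        grid = hg.make_grid(dev.tib_s)
        assign = hg.assign_intervals(dev, grid)
        ok = hg.device_quality_mask(dev).final_ok
        dur_prop = hg.validity_proportion(dev, assign, ok, grid)
        from hrvgate.segmentation import valid_counts

        counts = valid_counts(assign, ok, grid)
        totals = valid_counts(assign, np.ones(dev.n_intervals, bool), grid)
        count_prop = counts / np.maximum(totals, 1)
        assert not np.allclose(dur_prop, count_prop, atol=1e-3)


class TestCohort:
    def test_counts_and_group_labels(self):
        nights = hg.generate_cohort(hg.SimConfig(n_younger=2, n_older=1, seed=4))
        assert len(nights) == 3
        assert [n.group for n in nights] == ["younger", "younger", "older"]
        assert len({n.participant_id for n in nights}) == 3

    def test_presets_propagate(self):
        """Group presets reach the generated series: with between-subject
        spread disabled, the older group's configured lower HR shows up as
        longer mean intervals."""
        presets = hg.SimConfig().presets
        presets = {
            "younger": simulate.GroupPreset(
                **{**presets["younger"].__dict__, "hr_between_sd": 0.0}
            ),
            "older": simulate.GroupPreset(
                **{**presets["older"].__dict__, "hr_between_sd": 0.0}
            ),
        }
        cfg = hg.SimConfig(n_younger=2, n_older=2, tib_hours=1.0, presets=presets, seed=5)
        nights = hg.generate_cohort(cfg)
        mean_ibi = {
            g: np.mean(
                [n.reference.intervals.mean() for n in nights if n.group == g]
            )
            for g in ("younger", "older")
        }
        assert mean_ibi["older"] > mean_ibi["younger"]

    def test_cohort_deterministic_and_fast(self):
        import time

        t0 = time.time()
        a = hg.generate_cohort(hg.SimConfig(seed=12))
        elapsed = time.time() - t0
        b = hg.generate_cohort(hg.SimConfig(seed=12))
        assert elapsed < 60.0
        for na, nb in zip(a, b):
            np.testing.assert_array_equal(na.device.beat_times, nb.device.beat_times)
            np.testing.assert_array_equal(na.device.ratings, nb.device.ratings)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hg.SimConfig(lf_freq=0.2)
        with pytest.raises(ValueError):
            hg.SimConfig(hf_freq=0.5)
        with pytest.raises(ValueError):
            hg.SimConfig(tib_hours=0.0)
        with pytest.raises(ValueError):
            hg.SimConfig(n_younger=-1)
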