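"""Generator physiology: event scheduling, channel morphology, assembly."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import poisson

from apneakit import synthetic as syn


def _rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


OSA_ONLY = {"OSA": 1.0, "CSA": 0.0, "MSA": 0.0, "HYP": 0.0}


class TestScheduleEvents:
    def test_zero_rate_gives_no_events(self):
        assert syn.schedule_events(3600, 0.0, OSA_ONLY, np.random.default_rng(0)) == []

    def test_rejects_mix_not_summing_to_one(self):
        with pytest.raises(ValueError):
            syn.schedule_events(3600, 10, {"OSA": 0.6, "CSA": 0.3}, np.random.default_rng(0))

    def test_same_seed_same_schedule(self):
        a = syn.schedule_events(3600, 20, OSA_ONLY, np.random.default_rng(7))
        b = syn.schedule_events(3600, 20, OSA_ONLY, np.random.default_rng(7))
        assert a == b

    def test_counts_durations_and_gaps(self):
        """Mean count over 100 seeded nights falls in the Poisson 95%
        interval of the nominal rate; durations stay clinical; gaps >= 15 s."""
        counts = []
        for s in range(100):
            evs = syn.schedule_events(3600, 20, OSA_ONLY, np.random.default_rng(s))
            counts.append(len(evs))
            assert all(10.0 <= e.duration <= 120.0 for e in evs)
            assert all(e.event_class == "OSA" for e in evs)
            gaps = [b.onset - a.end for a, b in zip(evs, evs[1:])]
            assert all(g >= syn._MIN_GAP - 1e-9 for g in gaps)
        lo, hi = poisson.ppf(0.025, 20), poisson.ppf(0.975, 20)
        assert lo <= np.mean(counts) <= hi

    def test_duration_mode_in_typical_band(self):
        durs = []
        for s in range(50):
            durs += [e.duration for e in
                     syn.schedule_events(7200, 30, OSA_ONLY, np.random.default_rng(s))]
        frac_typical = np.mean([(20 <= d <= 40) for d in durs])
        assert 0.45 < frac_typical < 0.75  # log-normal tuned to ~0.6

    def test_class_frequencies_converge_to_mix(self):
        mix = {"OSA": 0.5, "CSA": 0.2, "MSA": 0.2, "HYP": 0.1}
        classes = []
        for s in range(60):
            classes += [e.event_class for e in
                        syn.schedule_events(7200, 30, mix, np.random.default_rng(s))]
        classes = np.array(classes)
        for c, p in mix.items():
            # runs are class-homogeneous, so tolerate run-level clustering
            assert abs(np.mean(classes == c) - p) < 0.08


class TestThoracic:
    def test_quiet_night_envelope_is_stable(self, profile):
        x = syn.synth_thoracic([], profile, 3600)
        env = np.sqrt(np.convolve(x**2, np.ones(1000) / 1000, mode="valid"))
        assert env.std() / env.mean() < 0.3

    @pytest.mark.parametrize("cls,lo,hi", [("CSA", 0.0, 0.1), ("OSA", 0.7, 2.0)])
    def test_event_rms_ratio(self, profile, cls, lo, hi):
        ev = syn.EventSpec(cls, 600, 30)
        x = syn.synth_thoracic([ev], profile, 1200)
        inside = _rms(x[600 * 100 : 630 * 100])
        outside = _rms(np.r_[x[: 590 * 100], x[650 * 100 :]])
        assert lo <= inside / outside <= hi

    def test_hyp_event_partial_reduction(self, profile):
        ev = syn.EventSpec("HYP", 600, 30)
        x = syn.synth_thoracic([ev], profile, 1200)
        ratio = _rms(x[600 * 100 : 630 * 100]) / _rms(np.r_[x[: 590 * 100], x[650 * 100 :]])
        assert 0.3 < ratio < 0.9

    def test_msa_central_then_obstructive(self, profile):
        ev = syn.EventSpec("MSA", 600, 60)
        x = syn.synth_thoracic([ev], profile, 1200)
        first = _rms(x[600 * 100 : 620 * 100])
        second = _rms(x[640 * 100 : 660 * 100])
        assert first < 0.3 * second

    def test_event_locality(self, profile):
        """Outside [onset-5, end+60] the signal is unchanged (to floating
        precision: the breathing-phase deficit is repaid in the recovery
        window, leaving only epsilon-level summation differences)."""
        ev = syn.EventSpec("OSA", 600, 30)
        with_ev = syn.synth_thoracic([ev], profile, 1200)
        without = syn.synth_thoracic([], profile, 1200)
        diff = np.abs(with_ev - without)
        window = np.zeros(len(diff), dtype=bool)
        window[(600 - 5) * 100 : (630 + 60) * 100] = True
        assert diff[~window].max() < 1e-6
        assert diff[window].max() > 0.1


class TestSpo2:
    def test_quiet_night_stays_near_baseline(self, profile):
        x = syn.synth_spo2([], profile, 3600)
        assert x.min() >= profile.baseline_spo2 - 1.5

    def test_desaturation_depth_and_latency(self, profile):
        ev = syn.EventSpec("OSA", 600, 30)
        x = syn.synth_spo2([ev], profile, 1200)
        t_min = np.argmin(x) / 100.0
        assert 610 <= t_min <= 680
        assert x.min() <= profile.baseline_spo2 - 3.0

    def test_event_response_is_local(self, profile):
        ev = syn.EventSpec("OSA", 600, 30)
        a = syn.synth_spo2([ev], profile, 1200)
        b = syn.synth_spo2([], profile, 1200)
        diff = np.flatnonzero(a != b)
        assert diff.min() >= 600 * 100
        assert diff.max() < (630 + 60) * 100

    def test_severity_ordering_of_desaturations(self, profile):
        """Mean desat depth: comparable for the three apnea types, all
        deeper than hypopnea."""
        depths = {}
        for cls in ("OSA", "CSA", "MSA", "HYP"):
            d = []
            for k in range(30):
                ev = syn.EventSpec(cls, 300 + 17 * k, 30)
                x = syn.synth_spo2([ev], profile, 900 + 17 * k)
                d.append(profile.baseline_spo2 - x.min())
            depths[cls] = np.mean(d)
        assert depths["HYP"] < min(depths["OSA"], depths["CSA"], depths["MSA"])
        apn = [depths["OSA"], depths["CSA"], depths["MSA"]]
        assert max(apn) - min(apn) < 0.75

    def test_values_clipped_to_physiologic_range(self, profile):
        evs = [syn.EventSpec("OSA", 60 + 45 * k, 30) for k in range(10)]
        x = syn.synth_spo2(evs, profile, 600)
        assert x.min() >= 70.0 and x.max() <= 100.0


class TestAncillary:
    def test_csa_silences_the_snore_trace(self, profile):
        ev = syn.EventSpec("CSA", 600, 30)
        audio = syn.synth_ancillary([ev], profile, 1200)["audio"]
        epoch_rms = [_rms(audio[k * 3000 : (k + 1) * 3000]) for k in range(40)]
        assert _rms(audio[600 * 100 : 630 * 100]) < 0.2 * np.median(epoch_rms)

    def test_rr_lengthens_then_shortens(self, profile):
        from apneakit.features import detect_beats

        ev = syn.EventSpec("OSA", 600, 30)
        ecg = syn.synth_ancillary([ev], profile, 1200)["ecg"]
        beats = detect_beats(ecg) / 100.0
        rr = np.diff(beats)
        mid = (beats[:-1] + beats[1:]) / 2
        in_event = rr[(mid >= 610) & (mid < 630)].mean()
        post = rr[(mid >= 630) & (mid < 640)].mean()
        assert post < in_event

    def test_eog_arousal_burst_after_event(self, profile):
        ev = syn.EventSpec("OSA", 600, 30)
        eog = syn.synth_ancillary([ev], profile, 1200)["eog_r"]
        sos = sps.butter(4, (13, 30), btype="band", fs=100, output="sos")
        beta = sps.sosfiltfilt(sos, eog)
        burst = _rms(beta[630 * 100 : 640 * 100])
        baseline = _rms(beta[300 * 100 : 310 * 100])
        assert burst > 2.0 * baseline

    def test_position_codes_in_declared_set(self, profile):
        pos = syn.synth_ancillary([], profile, 1200)["position"]
        assert set(np.unique(pos)).issubset(set(float(c) for c in syn.POSITION_CODES))


class TestGenerateRecording:
    def test_channel_lengths(self, short_recording):
        for x in short_recording.channels.values():
            assert len(x) == 180_000  # 0.5 h * 3600 s/h * 100 Hz

    def test_wake_epoch_count(self, short_recording):
        n_wake = int(short_recording.hypnogram.sum())
        assert abs(n_wake - round(0.1 * 60)) <= 1

    def test_wake_epochs_contain_no_events(self, short_recording):
        for k in np.flatnonzero(short_recording.hypnogram):
            for ev in short_recording.events:
                assert not (ev.onset < (k + 1) * 30 and ev.end > k * 30)

    def test_determinism(self, profile):
        a = syn.generate_recording(profile, 0.5, 20)
        b = syn.generate_recording(profile, 0.5, 20)
        assert a.events == b.events
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
        np.testing.assert_array_equal(a.hypnogram, b.hypnogram)

    def test_signals_on_16bit_grid(self, short_recording):
        for name, x in short_recording.channels.items():
            lo, hi = syn.CHANNEL_RANGES[name]
            step = (hi - lo) / (2**16 - 1)
            k = (x - lo) / step
            np.testing.assert_allclose(k, np.round(k), atol=1e-6)
            assert x.min() >= lo and x.max() <= hi

    def test_spectral_compliance_below_30hz(self, short_recording):
        for name in ("thoracic", "eog_l", "eog_r", "ecg", "audio"):
            f, p = sps.welch(short_recording.channels[name], fs=100, nperseg=4096)
            assert p[f <= 30].sum() / p.sum() > 0.99

    def test_invalid_ranges_rejected(self, profile):
        with pytest.raises(ValueError):
            syn.generate_recording(profile, 0.2)
        with pytest.raises(ValueError):
            syn.generate_recording(profile, 1.0, wake_fraction=0.8)

    def test_effect_size_zero_hides_events(self, profile):
        rec0 = syn.generate_recording(profile, 0.5, 20, effect_size=0.0)
        assert len(rec0.events) > 0
        quiet = syn.synth_spo2([], profile, 1800)
        planted = syn.synth_spo2(rec0.events, profile, 1800, effect_size=0.0)
        np.testing.assert_allclose(planted, quiet, atol=1e-9)
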