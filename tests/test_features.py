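"""Feature bank: elementary operations against closed forms and
brute-force oracles, and registry fidelity."""

import numpy as np
import pytest
import pywt

from apneakit import features as fb
from apneakit.preprocessing import Epoch

FS = 100
T30 = np.arange(3000) / FS


def make_epoch(**channels) -> Epoch:
    return Epoch("T0", 0, 0.0, {k: np.asarray(v, dtype=float) for k, v in channels.items()})


# ---------------------------------------------------------------------------
# independent oracles


def apen_oracle(x, m=2, r_frac=0.25):
    """Direct O(n^2) ApEn per the definition, self-matches included."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_frac * x.std()
    if x.std() == 0:
        return 0.0

    def phi(mm):
        vecs = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for v in vecs:
            c = sum(1 for w in vecs if np.max(np.abs(v - w)) <= r)
            total += np.log(c / len(vecs))
        return total / len(vecs)

    return phi(m) - phi(m + 1)


def delta_index_oracle(x, win_s=12):
    means = []
    w = win_s * FS
    for k in range(len(x) // w):
        means.append(np.mean(x[k * w : (k + 1) * w]))
    return float(np.mean([abs(a - b) for a, b in zip(means, means[1:])])) if len(means) > 1 else 0.0


_DB4_LO = np.array(pywt.Wavelet("db4").dec_lo)
_DB4_HI = np.array(pywt.Wavelet("db4").dec_hi)


def dwt_details_oracle(x, levels=5):
    """Convolution-and-decimate filter bank with periodic wrap (odd lengths
    padded by repeating the last sample)."""

    def step(v, f):
        if len(v) % 2 == 1:
            v = np.r_[v, v[-1]]
        n = len(v)
        return np.array(
            [sum(f[m] * v[(2 * k + 4 - m) % n] for m in range(len(f))) for k in range(n // 2)]
        )

    details, approx = [], np.asarray(x, float)
    for _ in range(levels):
        details.append(step(approx, _DB4_HI))
        approx = step(approx, _DB4_LO)
    return details  # d1 ... d5


# ---------------------------------------------------------------------------


class TestTimeStats:
    def test_basic_arithmetic(self):
        s = fb.time_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s["mean"] == 2.5 and s["median"] == 2.5
        assert s["iqr"] == pytest.approx(1.5)

    def test_constant_series(self):
        s = fb.time_stats(np.full(100, 3.3))
        assert s["std"] == 0.0 and s["skewness"] == 0.0

    def test_sine_rectified_area(self):
        x = np.sin(2 * np.pi * 0.25 * T30)
        # mean of |sin| is 2/pi, so the 30-s integral is 2/pi * 30
        assert fb.time_stats(x)["auc"] == pytest.approx(2 / np.pi * 30, rel=1e-3)


class TestPeakStats:
    def test_sine_peak_train(self):
        x = np.sin(2 * np.pi * 0.25 * T30)
        s = fb.peak_stats(x)
        assert s["n_peaks"] in (7, 8)
        assert s["mean_ipd"] == pytest.approx(4.0, abs=0.02)
        # peak height is measured from the epoch median
        assert s["mean_ph"] == pytest.approx(1.0 - np.median(x), abs=0.01)

    def test_constant_has_no_peaks(self):
        s = fb.peak_stats(np.full(3000, 2.0))
        assert s["n_peaks"] == 0 and s["ipd_flagged"] == 1.0

    def test_two_identical_peaks(self):
        x = np.zeros(3000)
        x[500:600] = np.sin(np.linspace(0, np.pi, 100))
        x[2000:2100] = np.sin(np.linspace(0, np.pi, 100))
        s = fb.peak_stats(x)
        assert s["n_peaks"] == 2 and s["std_ph"] == pytest.approx(0.0, abs=1e-12)


class TestSpectral:
    def test_tone_peak_frequency_within_bin(self):
        x = np.sin(2 * np.pi * 0.3 * T30)
        s = fb.spectral_stats(x, band=(0.0, 5.0))
        assert abs(s["peak_freq"] - 0.3) <= 0.25  # 4-s segments -> 0.25 Hz bins

    def test_tone_band_power_is_half(self):
        x = np.sin(2 * np.pi * 2.0 * T30)
        s = fb.spectral_stats(x, band=(0.0, 50.0))
        assert s["band_power"] == pytest.approx(0.5, abs=0.05)

    def test_white_noise_centroid_near_band_midpoint(self):
        mf = [
            fb.spectral_stats(np.random.default_rng(s).standard_normal(3000))["mean_freq"]
            for s in range(50)
        ]
        assert np.mean(mf) == pytest.approx(25.0, abs=1.0)

    def test_eog_rhythm_band_memberships(self):
        two = np.sin(2 * np.pi * 2.0 * T30)
        twenty = np.sin(2 * np.pi * 20.0 * T30)
        zero = np.zeros(3000)
        p = fb.eog_rhythm_power(two, two)
        assert p["delta_r"] == pytest.approx(0.5, abs=0.05)
        assert p["beta_r"] == pytest.approx(0.0, abs=1e-3)
        p = fb.eog_rhythm_power(zero, twenty)
        assert p["beta_r"] == pytest.approx(0.5, abs=0.05)
        assert fb.eog_rhythm_power(zero, zero)["delta_l"] == 0.0


class TestRenyiEntropy:
    def test_degenerate_single_bin(self):
        f = np.arange(10.0)
        p = np.zeros(10)
        p[3] = 2.0
        assert fb.renyi_entropy(None, psd=(f, p)) == 0.0

    def test_uniform_spectrum_log_k(self):
        f = np.arange(32.0)
        p = np.ones(32)
        assert fb.renyi_entropy(None, psd=(f, p)) == pytest.approx(np.log(32))

    def test_noise_exceeds_tone(self):
        diffs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            noise = rng.standard_normal(3000)
            tone = np.sin(2 * np.pi * 1.0 * T30 + rng.uniform(0, 2 * np.pi))
            diffs.append(fb.renyi_entropy(noise) - fb.renyi_entropy(tone))
        assert np.mean(diffs) > 0 and np.min(diffs) > 0


class TestApproximateEntropy:
    def test_constant_is_zero(self):
        assert fb.approximate_entropy(np.full(120, 5.0)) == 0.0

    @pytest.mark.parametrize("r_frac", [0.15, 0.25])
    def test_matches_direct_oracle(self, r_frac):
        rng = np.random.default_rng(99)
        for _ in range(10):
            x = rng.standard_normal(120)
            assert fb.approximate_entropy(x, 2, r_frac) == pytest.approx(
                apen_oracle(x, 2, r_frac), abs=1e-9
            )

    def test_noise_more_irregular_than_periodic(self):
        rng = np.random.default_rng(5)
        period4 = np.tile([0.0, 1.0, 0.0, -1.0], 30)
        noise = rng.standard_normal(120) * period4.std()
        assert fb.approximate_entropy(noise) > fb.approximate_entropy(period4)

    def test_dc_offset_invariance(self):
        x = np.random.default_rng(3).standard_normal(120)
        assert fb.approximate_entropy(x + 100.0) == pytest.approx(
            fb.approximate_entropy(x), abs=1e-12
        )


class TestSpo2Features:
    def test_constant_saturation(self):
        s = fb.spo2_features(np.full(3000, 97.0))
        assert s["delta_index"] == 0.0 and s["tsa95"] == 0.0 and s["m2"] == 0.0

    def test_half_epoch_below_threshold(self):
        x = np.r_[np.full(1500, 96.0), np.full(1500, 93.0)]
        assert fb.spo2_features(x)["tsa95"] == 0.5

    def test_step_delta_index_matches_enumeration(self):
        x = np.r_[np.full(1500, 97.0), np.full(1500, 93.0)]
        s = fb.spo2_features(x)
        assert s["delta_index"] == pytest.approx(delta_index_oracle(x), abs=1e-12)
        assert s["delta_index"] == pytest.approx(3.0)

    def test_dc_offset_invariance_of_spread_stats(self):
        x = 95 + np.random.default_rng(1).standard_normal(3000)
        a, b = fb.spo2_features(x), fb.spo2_features(x + 2.0)
        for key in ("std", "range", "m2", "delta_index"):
            assert a[key] == pytest.approx(b[key], abs=1e-9)


class TestISE:
    def test_silent_epoch(self):
        s = fb.ise_features(np.zeros(3000))
        assert s["ise_range"] == 0.0

    def test_stationary_noise_is_calm(self):
        ranges, outside = [], []
        for s in range(50):
            r = fb.ise_features(np.random.default_rng(s).standard_normal(3000))
            ranges.append(r["ise_range"])
            outside.append(r["time_outside"])
        assert np.mean(outside) <= 0.1

    def test_tone_to_noise_transition_widens_range(self):
        rng = np.random.default_rng(4)
        stationary = rng.standard_normal(3000)
        tone_then_noise = np.r_[
            np.sin(2 * np.pi * 5 * T30[:1500]), rng.standard_normal(1500)
        ]
        assert (
            fb.ise_features(tone_then_noise)["ise_range"]
            > fb.ise_features(stationary)["ise_range"]
        )


class TestDWT:
    def test_zero_signal_zero_features(self):
        out = fb.ecg_dwt_features(np.zeros(3000))
        assert all(v == 0.0 for v in out.values())

    def test_scaling_homogeneity(self):
        x = np.random.default_rng(7).standard_normal(3000)
        a, b = fb.ecg_dwt_features(x), fb.ecg_dwt_features(3.0 * x)
        for k in a:
            power = 2 if k.startswith("dwt_var") else 1
            assert b[k] == pytest.approx(3.0**power * a[k], rel=1e-9)

    def test_details_match_filter_bank_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            x = rng.standard_normal(3000)
            mine = fb.dwt_details(x)
            oracle = dwt_details_oracle(x)
            for d_mine, d_oracle in zip(mine, oracle):
                np.testing.assert_allclose(d_mine, d_oracle, atol=1e-9)

    def test_audio_detail_energy(self):
        x = np.random.default_rng(2).standard_normal(3000)
        out = fb.audio_dwt_energy(x)
        d = dwt_details_oracle(x)
        assert out["dwt_energy_d3"] == pytest.approx(np.sum(d[2] ** 2), abs=1e-9)
        assert out["dwt_energy_d4"] == pytest.approx(np.sum(d[3] ** 2), abs=1e-9)


class TestRRFeatures:
    @staticmethod
    def beat_train(bpm, duration_s=30, noise=0.0, seed=0):
        from apneakit.synthetic import _qrs_template

        rng = np.random.default_rng(seed)
        x = noise * rng.standard_normal(duration_s * FS)
        tmpl = _qrs_template()
        period = 60.0 / bpm
        t = 0.3
        while t < duration_s - 0.2:
            k = int(t * FS)
            x[k : k + len(tmpl)] += tmpl
            t += period
        return x

    def test_sixty_bpm_train(self):
        s = fb.rr_features(self.beat_train(60, noise=0.02))
        assert s["mean_rr"] == pytest.approx(1.0, abs=0.01)

    def test_seventy_five_bpm_train(self):
        s = fb.rr_features(self.beat_train(75, noise=0.02))
        assert s["mean_rr"] == pytest.approx(0.8, abs=0.01)
        assert s["median_rr"] == pytest.approx(0.8, abs=0.01)

    def test_too_few_beats_flagged(self):
        s = fb.rr_features(np.zeros(3000))
        assert np.isnan(s["mean_rr"]) and np.isnan(s["median_rr"])


class TestRegistries:
    def test_detection_subset_size_and_composition(self):
        names = fb.registry_names("b32")
        assert len(names) == 32 and len(set(names)) == 32
        by_signal = {}
        for fd in fb.DETECTION_32:
            by_signal[fd.signal] = by_signal.get(fd.signal, 0) + 1
        assert by_signal == {"thoracic": 16, "spo2": 9, "audio": 4, "eog": 3}

    def test_distinction_subset_size_and_composition(self):
        names = fb.registry_names("iii44")
        assert len(names) == 44 and len(set(names)) == 44
        by_signal = {}
        for fd in fb.DISTINCTION_44:
            by_signal[fd.signal] = by_signal.get(fd.signal, 0) + 1
        assert by_signal == {"ecg": 18, "thoracic": 12, "spo2": 9, "audio": 4, "position": 1}

    def test_full_bank_contains_both_subsets(self):
        full = set(fb.registry_names("full"))
        assert set(fb.registry_names("b32")) <= full
        assert set(fb.registry_names("iii44")) <= full


class TestExtraction:
    @staticmethod
    def epoch_with_all_channels(seed=0):
        rng = np.random.default_rng(seed)
        return make_epoch(
            thoracic=np.sin(2 * np.pi * 0.25 * T30) * (1 + 0.1 * rng.standard_normal(3000)),
            spo2=96 + 0.3 * rng.standard_normal(3000),
            audio=np.abs(rng.standard_normal(3000)) * 0.2,
            eog_l=rng.standard_normal(3000),
            eog_r=rng.standard_normal(3000),
            ecg=TestRRFeatures.beat_train(65, noise=0.02, seed=seed),
            position=np.zeros(3000),
        )

    @pytest.mark.parametrize("registry_id,size", [("b32", 32), ("iii44", 44)])
    def test_vector_length_and_order(self, registry_id, size):
        ep = self.epoch_with_all_channels()
        vec = fb.extract_features(ep, registry_id)
        assert list(vec) == fb.registry_names(registry_id)
        assert len(vec) == size

    def test_deterministic(self):
        ep = self.epoch_with_all_channels()
        assert fb.extract_features(ep, "b32") == fb.extract_features(ep, "b32")

    def test_missing_channel_is_a_hard_error(self):
        ep = make_epoch(thoracic=np.zeros(3000))
        with pytest.raises(KeyError, match="spo2"):
            fb.extract_features(ep, "b32")

    def test_excluded_epoch_rejected(self):
        ep = self.epoch_with_all_channels()
        ep.excluded = True
        with pytest.raises(ValueError):
            fb.extract_features(ep, "b32")

    def test_position_majority_code(self):
        pos = np.r_[np.full(1000, 2.0), np.full(2000, 3.0)]
        assert fb.position_code(pos) == 3.0

    def test_imputation_uses_training_median(self):
        import pandas as pd

        table = pd.DataFrame(
            {"f": [1.0, 3.0, np.nan, 10.0], "subject_id": list("abcd")}
        )
        train = np.array([True, True, False, False])
        out, mask = fb.impute_with_train_median(table, train, ["f"])
        assert out["f"].tolist() == [1.0, 3.0, 2.0, 10.0]
        assert mask["f"].tolist() == [False, False, True, False]
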