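import numpy as np
import pytest

from comfnet.preprocessing import (
    BANDS,
    EpochSet,
    MultichannelRecording,
    condition_recording,
    default_wpt_level,
    epoch_recording,
    extract_band,
    label_comfort,
    reject_artifacts,
)


def make_recording(data, fs=250.0):
    labels = [f"E{i:03d}" for i in range(data.shape[0])]
    return MultichannelRecording(np.asarray(data, float), fs, labels)


def tone(freq, fs=250.0, seconds=10.0, n_channels=2):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))


def band_power(x, fs, f0, half_width=1.0):
    freqs = np.fft.rfftfreq(x.shape[-1], 1 / fs)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    sel = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    return spec[..., sel].sum()


class TestConditioning:
    def test_notch_attenuates_mains_tone_40db(self):
        rec = make_recording(tone(50.0, seconds=20.0))
        out = condition_recording(rec, reref="none", bp=None, notch=50.0)
        # steady state: discard 2 s of forward-backward filter transients
        cut = slice(2 * 250, -2 * 250)
        p_in = band_power(rec.data[:, cut], rec.fs, 50.0, 0.5)
        p_out = band_power(out.data[:, cut], out.fs, 50.0, 0.5)
        assert 10 * np.log10(p_in / p_out) >= 40.0

    def test_highpass_removes_dc_offset(self):
        # 600 s record with distinct constant offsets per channel
        data = np.ones((3, int(600 * 250))) * np.array([[10.0], [-5.0], [2.5]])
        out = condition_recording(make_recording(data), reref="none",
                                  bp=(0.01, 40.0), notch=None)
        assert np.all(np.abs(out.data.mean(axis=1)) < 0.1)

    def test_identity_when_everything_disabled(self):
        rec = make_recording(tone(10.0))
        out = condition_recording(rec, reref="none", fs_target=rec.fs,
                                  bp=None, notch=None)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_resampling_changes_rate_and_preserves_tone(self):
        rec = make_recording(tone(10.0, fs=500.0), fs=500.0)
        out = condition_recording(rec, reref="none", fs_target=250.0,
                                  bp=None, notch=None)
        assert out.fs == 250.0
        assert out.data.shape[1] == rec.data.shape[1] // 2

    def test_bandpass_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            condition_recording(make_recording(tone(10.0)), bp=(0.01, 130.0),
                                notch=None)


class TestEpoching:
    @pytest.mark.parametrize("seconds,expected", [(600.0, 300), (601.0, 300)])
    def test_epoch_counts_with_partial_drop(self, seconds, expected):
        rec = make_recording(np.zeros((2, int(seconds * 250))))
        ep = epoch_recording(rec, epoch_length=2.0)
        assert ep.n_epochs == expected

    def test_window_ids(self):
        rec = make_recording(np.zeros((1, int(600 * 250))))
        ep = epoch_recording(rec, epoch_length=2.0, window_length=600.0)
        assert set(ep.window_id.tolist()) == {0}
        ep2 = epoch_recording(rec, epoch_length=2.0, window_length=60.0)
        assert ep2.window_id.tolist() == sorted(ep2.window_id.tolist())
        assert set(ep2.window_id.tolist()) == set(range(10))

    def test_non_multiple_window_rejected(self):
        rec = make_recording(np.zeros((1, 2500)))
        with pytest.raises(ValueError, match="multiple"):
            epoch_recording(rec, epoch_length=2.0, window_length=5.0)


class TestArtifactRejection:
    def test_spiked_epoch_removed_and_counts_conserved(self):
        rec = make_recording(np.zeros((2, 2500)))
        ep = epoch_recording(rec, epoch_length=2.0)  # 5 epochs
        data = ep.data.copy()
        data[2, 1, 100] = 500.0
        ep = EpochSet(data, ep.fs, ep.channel_labels, ep.window_id)
        out = reject_artifacts(ep, peak_to_peak_max=100.0)
        assert out.n_epochs == 4
        info = out.meta["artifact_rejection"]
        assert info["n_in"] == out.n_epochs + info["n_rejected"] == 5

    def test_clean_set_unchanged_and_zero_threshold_rejected(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 2500)))
        ep = epoch_recording(rec, epoch_length=2.0)
        assert reject_artifacts(ep, 1e9).n_epochs == ep.n_epochs
        with pytest.raises(ValueError):
            reject_artifacts(ep, 0.0)


class TestBandExtraction:
    def test_level_default_fits_narrowest_band(self):
        assert 250.0 / 2 ** (default_wpt_level(250.0) + 1) <= 2.0

    @pytest.mark.parametrize("freq,band,low,high", [
        (20.0, "beta", 0.90, 1.01),   # in-band tone mostly retained
        (5.0, "beta", 0.0, 0.10),     # out-of-band tone mostly removed
        (2.0, "delta", 0.90, 1.01),
    ])
    def test_tone_energy_ratio(self, freq, band, low, high):
        rec = make_recording(tone(freq, seconds=8.0))
        ep = epoch_recording(rec, epoch_length=2.0)
        out = extract_band(ep, band)
        ratio = np.sum(out.data**2) / np.sum(ep.data**2)
        assert low <= ratio <= high
        assert out.band == band

    def test_zero_signal_maps_to_zero(self):
        ep = epoch_recording(make_recording(np.zeros((2, 2500))), 2.0)
        assert np.allclose(extract_band(ep, "beta").data, 0.0)

    def test_band_energies_partition_broadband_noise(self):
        rng = np.random.default_rng(11)
        rec = make_recording(rng.normal(size=(2, 250 * 40)))
        rec = condition_recording(rec, reref="none", bp=(1.0, 40.0), notch=None)
        ep = epoch_recording(rec, epoch_length=2.0)
        total = np.sum(ep.data**2)
        with pytest.warns(UserWarning, match="gamma"):
            band_sum = sum(np.sum(extract_band(ep, b).data**2) for b in BANDS)
        assert abs(band_sum / total - 1.0) < 0.10

    def test_second_extraction_is_near_idempotent(self):
        rng = np.random.default_rng(5)
        ep = epoch_recording(make_recording(rng.normal(size=(2, 10000))), 4.0)
        once = extract_band(ep, "beta")
        twice = extract_band(once, "beta")
        e1, e2 = np.sum(once.data**2), np.sum(twice.data**2)
        assert abs(e2 / e1 - 1.0) < 0.01

    def test_gamma_on_lowpassed_data_warns_not_errors(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 5000)))
        rec = condition_recording(rec, reref="none", bp=(0.01, 40.0), notch=None)
        ep = epoch_recording(rec, 2.0)
        with pytest.warns(UserWarning, match="gamma"):
            extract_band(ep, "gamma")


class TestComfortLabels:
    def test_sign_rule_and_neutral_band(self):
        labels = label_comfort({0: 30.0, 1: -30.0, 2: 0.0}, neutral_band=5.0)
        assert labels == {0: "comfortable", 1: "uncomfortable", 2: "excluded"}

    def test_zero_band_sign_rule(self):
        assert label_comfort({0: 0.5})[0] == "comfortable"
        assert label_comfort({0: -0.5})[0] == "uncomfortable"
        assert label_comfort({0: 0.0})[0] == "excluded"

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValueError, match="VAS"):
            label_comfort({0: 60.0})

    def test_epochset_label_join(self):
        rec = make_recording(np.zeros((1, 2500)))
        ep = epoch_recording(rec, 2.0, window_length=4.0)
        labelled = ep.with_comfort_labels(label_comfort({0: 10.0, 1: -10.0}))
        assert labelled.comfort_label[0] == "comfortable"
        assert labelled.comfort_label[-1] in ("uncomfortable", "excluded")
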