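"""Downsampling, epoching, artifact rejection, band power."""

import numpy as np
import pytest
from scipy import signal

from alphastates import (
    RawEEG,
    alpha_power,
    downsample,
    reject_artifact_epochs,
    segment_epochs,
)
from alphastates.preprocess import ArtifactRateWarning, epoch_band_power, power_pipeline


def sinusoid_raw(freq=10.0, amp=10.0, fs=1000, seconds=10, channels=("AF3", "AF4")):
    t = np.arange(int(fs * seconds)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return RawEEG(np.tile(x, (len(channels), 1)), fs, list(channels))


class TestDownsample:
    def test_decimation_factor_four(self):
        raw = RawEEG(np.zeros((2, 10_000)), 1000, ["AF3", "AF4"])
        out = downsample(raw, 250)
        assert out.sampling_rate == 250
        assert out.n_samples == 2500

    def test_identity_rate_returns_same_signal(self):
        raw = sinusoid_raw(fs=250, seconds=2)
        out = downsample(raw, 250)
        np.testing.assert_array_equal(out.samples, raw.samples)

    def test_sub_nyquist_amplitude_preserved(self):
        raw = sinusoid_raw(freq=10, amp=10, fs=1000, seconds=10)
        out = downsample(raw, 250)
        # compare steady-state RMS away from filter edges with the analytic value
        mid = out.samples[0, 250:-250]
        amp_est = np.sqrt(2) * mid.std()
        assert amp_est == pytest.approx(10.0, rel=0.01)

    def test_non_integer_factor_rejected(self):
        raw = RawEEG(np.zeros((1, 1000)), 1000, ["AF3"])
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(raw, 300)


class TestSegmentEpochs:
    def test_two_minute_recording_gives_120_epochs(self):
        raw = RawEEG(np.zeros((2, 120 * 250)), 250, ["AF3", "AF4"])
        assert segment_epochs(raw).shape == (120, 2, 250)

    @pytest.mark.parametrize("n_samples,expected", [(625, 2), (250, 1)])
    def test_floor_rule_discards_trailing_partial(self, n_samples, expected):
        raw = RawEEG(np.zeros((1, n_samples)), 250, ["AF3"])
        assert segment_epochs(raw).shape[0] == expected

    def test_shorter_than_one_epoch_is_an_error(self):
        raw = RawEEG(np.zeros((1, 249)), 250, ["AF3"])
        with pytest.raises(ValueError, match="shorter than one"):
            segment_epochs(raw)


class TestArtifactRejection:
    def test_clean_epochs_pass(self):
        rng = np.random.default_rng(0)
        epochs = 30 * rng.uniform(-1, 1, size=(50, 2, 250))
        retained, mask = reject_artifact_epochs(epochs, 100.0)
        assert mask.sum() == 0
        assert retained.shape[0] == 50
        assert mask.size == 50  # one flag per original epoch

    def test_planted_spike_is_flagged(self):
        epochs = np.zeros((20, 2, 250))
        epochs[7, 1, 100] = 500.0
        retained, mask = reject_artifact_epochs(epochs, 100.0)
        assert list(np.flatnonzero(mask)) == [7]
        assert retained.shape[0] == 19

    def test_over_ten_percent_flagged_warns(self):
        rng = np.random.default_rng(1)
        epochs = 10 * rng.standard_normal((40, 1, 100))
        planted = [0, 5, 10, 15, 20, 25]  # 15%
        epochs[planted, 0, 3] = 400.0
        with pytest.warns(ArtifactRateWarning):
            _, mask = reject_artifact_epochs(epochs, 100.0)
        assert sorted(np.flatnonzero(mask)) == planted


class TestAlphaPower:
    def test_pure_alpha_sinusoid_total_power(self):
        """All spectral power sits at 10 Hz; total power equals a^2/2 = 50 uV^2."""
        raw = sinusoid_raw(freq=10, amp=10, fs=250, seconds=4)
        epochs = segment_epochs(raw)
        band_total = epoch_band_power(epochs, 250, band=(8, 13), agg="sum")
        full_total = epoch_band_power(epochs, 250, band=(1, 124), agg="sum")
        np.testing.assert_allclose(band_total, 50.0, rtol=0.01)
        np.testing.assert_allclose(band_total, full_total, rtol=0.01)

    def test_out_of_band_sinusoid_contributes_nothing(self):
        raw = sinusoid_raw(freq=20, amp=10, fs=250, seconds=4)
        epochs = segment_epochs(raw)
        band = epoch_band_power(epochs, 250, band=(8, 13), agg="sum")
        total = epoch_band_power(epochs, 250, band=(1, 124), agg="sum")
        assert (band <= 0.01 * total).all()

    def test_parseval_total_power_equals_mean_square(self):
        """Spectrum bins of an undetrended periodogram total the time-domain mean square."""
        rng = np.random.default_rng(2)
        epochs = rng.standard_normal((5, 2, 250))
        freqs, pxx = signal.periodogram(epochs, fs=250, window="boxcar",
                                        scaling="spectrum", detrend=False, axis=-1)
        total = pxx.sum(axis=-1)
        ms = np.mean(epochs**2, axis=-1)
        np.testing.assert_allclose(total, ms, rtol=1e-6)

    def test_missing_channel_error_names_it(self):
        raw = RawEEG(np.zeros((2, 500)), 250, ["AF3", "AF4"])
        with pytest.raises(KeyError, match="Cz"):
            raw.pick(["Cz"])

    def test_band_must_be_inside_nyquist(self):
        epochs = np.zeros((2, 1, 250))
        with pytest.raises(ValueError):
            epoch_band_power(epochs, 250, band=(8, 200))

    def test_power_non_negative_and_mask_bookkeeping(self):
        rng = np.random.default_rng(3)
        epochs = rng.standard_normal((10, 2, 250))
        mask = np.zeros(12, dtype=bool)
        mask[[2, 9]] = True
        ps = alpha_power(epochs, 250, rejected_mask=mask)
        assert (ps.values >= 0).all()
        assert ps.rejected_mask.size == 12
        assert ps.n_epochs == 10


class TestPipelineProperties:
    def test_downsample_then_power_matches_original(self):
        """Band power of a sub-Nyquist sinusoid is preserved by decimation (within 2%)."""
        raw = sinusoid_raw(freq=11, amp=8, fs=1000, seconds=12)
        hi = epoch_band_power(segment_epochs(raw), 1000, agg="sum")
        lo = epoch_band_power(segment_epochs(downsample(raw, 250)), 250, agg="sum")
        # ignore the filter-edge epochs at either end
        np.testing.assert_allclose(lo[2:-2], hi[2:-2], rtol=0.02)

    def test_power_pipeline_is_deterministic(self):
        rng = np.random.default_rng(4)
        raw = RawEEG(rng.standard_normal((2, 8000)), 1000, ["AF3", "AF4"])
        a = power_pipeline(raw)
        b = power_pipeline(raw)
        np.testing.assert_array_equal(a.values, b.values)
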