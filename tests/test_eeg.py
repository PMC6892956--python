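import numpy as np
import pytest

from nvfuse.containers import (
    InsufficientDataError,
    ParameterError,
    TimeSeriesRecording,
    ValidationError,
)
from nvfuse import eeg as E

from conftest import make_sine_recording


class TestBandRegistry:
    def test_canonical_bands(self):
        expected = {
            "delta": (1.5, 4.0), "theta": (4.0, 8.0), "lower_alpha": (8.0, 10.0),
            "upper_alpha": (10.0, 13.0), "beta": (14.0, 30.0), "gamma": (30.0, 50.0),
        }
        assert {n: (b.low_hz, b.high_hz) for n, b in E.BANDS.items()} == expected

    def test_bands_cover_range_without_overlap(self):
        bands = sorted(E.BANDS.values(), key=lambda b: b.low_hz)
        assert bands[0].low_hz == 1.5 and bands[-1].high_hz == 50.0
        for a, b in zip(bands, bands[1:]):
            assert b.low_hz >= a.high_hz  # shared edges allowed, no overlap

    def test_invalid_edges(self):
        with pytest.raises(ParameterError):
            E.BandDefinition("bad", 10.0, 8.0)


class TestOcularCorrection:
    def test_planted_eog_removed(self, rng):
        n = 256 * 20
        veog = rng.standard_normal(n) * 100
        clean = rng.standard_normal((3, n)) * 10
        scalp = clean.copy()
        scalp[0] += 0.7 * veog
        rec = TimeSeriesRecording(data=scalp, fs=256.0,
                                  channel_labels=["a", "b", "c"], modality="eeg")
        eog = TimeSeriesRecording(data=veog[None, :], fs=256.0,
                                  channel_labels=["VEOG"], modality="eog")
        out = E.correct_ocular(rec, eog)
        assert abs(np.corrcoef(out.data[0], veog)[0, 1]) <= 0.01
        # residuals orthogonal to the EOG channel
        resid = out.data - out.data.mean(axis=1, keepdims=True)
        ip = resid @ (veog - veog.mean())
        assert np.all(np.abs(ip) <= 1e-6 * np.linalg.norm(resid, axis=1)
                      * np.linalg.norm(veog - veog.mean()) + 1e-9)

    def test_zero_eog_leaves_recording_unchanged(self, eeg_recording):
        eog = TimeSeriesRecording(
            data=np.zeros((1, eeg_recording.n_samples)), fs=256.0,
            channel_labels=["VEOG"], modality="eog",
        )
        out = E.correct_ocular(eeg_recording, eog)
        np.testing.assert_allclose(out.data, eeg_recording.data, atol=1e-9)

    def test_fs_mismatch(self, eeg_recording):
        eog = TimeSeriesRecording(
            data=np.zeros((1, eeg_recording.n_samples)), fs=2048.0,
            channel_labels=["VEOG"], modality="eog",
        )
        with pytest.raises(ValidationError, match="fs mismatch"):
            E.correct_ocular(eeg_recording, eog)


class TestBandpass:
    @pytest.mark.parametrize("freq,lo,hi", [(9.0, 0.95, 1.05), (20.0, 0.0, 0.05)])
    def test_gain_in_and_out_of_band(self, freq, lo, hi):
        rec = make_sine_recording(freq, 256, 20)
        out = E.bandpass_band(rec, E.BANDS["lower_alpha"])
        # measure amplitude away from filtfilt edge transients
        seg = out.data[0, 1280:-1280]
        amp = np.sqrt(2) * seg.std()
        assert lo <= amp <= hi

    def test_dc_blocked(self):
        rec = TimeSeriesRecording(data=np.full((1, 5120), 3.0), fs=256.0,
                                  channel_labels=["a"], modality="eeg")
        out = E.bandpass_band(rec, E.BANDS["lower_alpha"])
        assert np.abs(out.data).max() <= 1e-6

    def test_zero_phase(self):
        rec = make_sine_recording(9.0, 256, 20)
        out = E.bandpass_band(rec, E.BANDS["lower_alpha"])
        xc = np.correlate(out.data[0, 1280:-1280], rec.data[0, 1280:-1280], "full")
        assert np.argmax(xc) == len(xc) // 2  # peak at lag 0

    def test_edge_at_nyquist(self):
        rec = make_sine_recording(9.0, 64, 5)
        with pytest.raises(ParameterError):
            E.bandpass_band(rec, E.BANDS["gamma"])  # 50 Hz >= 32 Hz


class TestResample:
    def test_2048_to_256_length(self, rng):
        rec = TimeSeriesRecording(data=rng.standard_normal((2, 2048)), fs=2048.0,
                                  channel_labels=["a", "b"], modality="eeg")
        out = E.resample(rec, 256.0)
        assert out.fs == 256.0 and out.n_samples == 256

    def test_50_to_5_length(self, rng):
        rec = TimeSeriesRecording(data=rng.standard_normal((1, 500)), fs=50.0,
                                  channel_labels=["a"], modality="eeg")
        out = E.resample(rec, 5.0)
        assert out.fs == 5.0 and out.n_samples == 50

    def test_identity(self, eeg_recording):
        out = E.resample(eeg_recording, eeg_recording.fs)
        np.testing.assert_array_equal(out.data, eeg_recording.data)

    def test_tone_survives_decimation(self):
        rec = make_sine_recording(9.0, 2048, 10)
        out = E.resample(rec, 256.0)
        amp = np.sqrt(2) * out.data[0, 256:-256].std()
        assert abs(amp - 1.0) <= 0.02

    def test_upsampling_rejected(self, eeg_recording):
        with pytest.raises(ParameterError):
            E.resample(eeg_recording, 512.0)

    def test_non_integer_ratio_needs_flag(self, eeg_recording):
        with pytest.raises(ParameterError):
            E.resample(eeg_recording, 100.0)
        out = E.resample(eeg_recording, 100.0, allow_rational=True)
        assert out.fs == 100.0


class TestEpoching:
    def _recording(self, rng, dur_s=660, fs=256, n_ch=3, amp=20.0):
        data = rng.standard_normal((n_ch, int(dur_s * fs))) * amp
        return TimeSeriesRecording(data=data, fs=float(fs),
                                   channel_labels=[f"c{i}" for i in range(n_ch)],
                                   modality="eeg")

    def test_clean_recording_yields_5120_samples(self, rng):
        rec = self._recording(rng)
        ep = E.epoch_and_reject(rec)
        assert ep.data.shape == (10, 3, 512)
        assert ep.n_epochs * ep.data.shape[2] == 5120
        assert ep.kept_epoch_indices == list(range(10))
        assert ep.t0 == pytest.approx(120.0)
        # baseline-corrected per channel
        assert np.abs(ep.data.mean(axis=2)).max() <= 1e-9

    def test_spike_epoch_excluded(self, rng):
        rec = self._recording(rng, dur_s=150)
        # place a 200 uV spike inside epoch 2 (after the 120 s lead)
        spike_at = int((120 + 2 * 2 + 0.5) * 256)
        rec.data[1, spike_at] = 200.0
        ep = E.epoch_and_reject(rec, n_keep=10)
        assert 2 not in ep.kept_epoch_indices
        assert ep.kept_epoch_indices == [0, 1, 3, 4, 5, 6, 7, 8, 9, 10]

    def test_all_zero_recording(self):
        rec = TimeSeriesRecording(data=np.zeros((2, 150 * 256)), fs=256.0,
                                  channel_labels=["a", "b"], modality="eeg")
        ep = E.epoch_and_reject(rec)
        assert ep.n_epochs == 10
        assert np.all(ep.data == 0)

    def test_insufficient_clean_epochs(self, rng):
        rec = self._recording(rng, dur_s=150, amp=200.0)  # everything exceeds 150 uV
        with pytest.raises(InsufficientDataError, match="0 artifact-free"):
            E.epoch_and_reject(rec)

    def test_deterministic(self, rng):
        rec = self._recording(rng, dur_s=150)
        a = E.epoch_and_reject(rec)
        b = E.epoch_and_reject(rec)
        assert a.kept_epoch_indices == b.kept_epoch_indices
        np.testing.assert_array_equal(a.data, b.data)

    def test_epoch_select_shares_indices(self, rng):
        rec = self._recording(rng, dur_s=150)
        sel = E.epoch_and_reject(rec)
        band = E.bandpass_band(rec, E.BANDS["theta"])
        ep = E.epoch_select(band, sel.kept_epoch_indices)
        assert ep.kept_epoch_indices == sel.kept_epoch_indices
        assert ep.data.shape == sel.data.shape
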