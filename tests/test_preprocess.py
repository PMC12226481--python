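"""Preprocessing chain: FIR bandpass, CAR, resampling, epoching, container I/O."""

import h5py
import numpy as np
import pytest

from fnssir.epochs import (EpochSet, FormatError, PreprocessConfig,
                           bandpass_fir, common_average_reference, crop,
                           extract_epochs, read_epochs, resample_to,
                           write_epochs)

FS = 200.0
T = np.arange(int(60 * FS)) / FS   # long enough for the 0.1 Hz transition


class TestBandpass:
    def test_stopband_tone_suppressed(self):
        """A 50 Hz tone is outside the 0.1-30 Hz band: residual RMS < 5%."""
        x = np.sin(2 * np.pi * 50.0 * T)[None, :]
        y = bandpass_fir(x, FS)
        # exclude the edge transient of the long zero-phase filter
        interior = slice(int(20 * FS), -int(20 * FS))
        assert np.sqrt(np.mean(y[0, interior]**2)) < \
            0.05 * np.sqrt(np.mean(x[0, interior]**2))

    def test_passband_tone_preserved(self):
        x = np.sin(2 * np.pi * 10.0 * T)[None, :]
        y = bandpass_fir(x, FS)
        interior = slice(int(2 * FS), -int(2 * FS))
        rms_ratio = np.sqrt(np.mean(y[0, interior]**2) / np.mean(x[0, interior]**2))
        assert abs(rms_ratio - 1.0) < 0.05

    def test_zero_input_zero_output(self):
        assert np.allclose(bandpass_fir(np.zeros((2, 14000)), FS), 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros((1, 4000)), 50.0,
                         PreprocessConfig(band_hi=30.0))

    def test_commutes_with_car(self, rng):
        """Both operators are linear (per-channel vs per-sample), so order
        must not matter."""
        x = rng.standard_normal((4, 14000))
        a = common_average_reference(bandpass_fir(x, FS))
        b = bandpass_fir(common_average_reference(x), FS)
        assert np.allclose(a, b, rtol=1e-9, atol=1e-9 * np.abs(a).max())


class TestCAR:
    def test_two_channel_example(self):
        x = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        y = common_average_reference(x)
        assert np.allclose(y, [[-1, -1, -1], [1, 1, 1]])

    def test_channel_mean_is_zero(self, rng):
        y = common_average_reference(rng.standard_normal((7, 100)))
        assert np.allclose(y.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent_on_zero_mean_input(self, rng):
        x = common_average_reference(rng.standard_normal((5, 50)))
        assert np.allclose(common_average_reference(x), x)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(np.ones((1, 10)))


class TestResample:
    def test_12s_at_1000_to_100(self):
        y = resample_to(np.zeros((2, 12000)), 1000.0, 100.0)
        assert y.shape == (2, 1200)

    def test_identity_when_rates_equal(self, rng):
        x = rng.standard_normal((2, 500))
        assert np.array_equal(resample_to(x, 100.0, 100.0), x)

    def test_sinusoid_preserved(self):
        t = np.arange(10000) / 1000.0
        y = resample_to(np.sin(2 * np.pi * 5 * t)[None], 1000.0, 100.0)[0]
        ideal = np.sin(2 * np.pi * 5 * np.arange(1000) / 100.0)
        sl = slice(50, -50)
        r = np.corrcoef(y[sl], ideal[sl])[0, 1]
        assert r > 0.999

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_to(np.zeros((1, 10)), 100.0, 0.0)


class TestExtractEpochs:
    CFG = PreprocessConfig(epoch_window=(0.0, 1.0), baseline_window=(-0.2, 0.0))

    def test_constant_offset_removed(self):
        x = np.full((2, 500), 7.5)
        ep = extract_epochs(x, 100.0, [100, 200], self.CFG)
        assert np.allclose(ep.data, 0.0)

    def test_one_epoch_per_onset(self, rng):
        x = rng.standard_normal((3, 50000))
        onsets = np.arange(126) * 300 + 200
        ep = extract_epochs(x, 100.0, onsets, self.CFG)
        assert ep.n_trials == 126

    def test_epoch_length_12s_at_100hz(self, rng):
        cfg = PreprocessConfig(epoch_window=(0.0, 12.0),
                               baseline_window=(-1.0, 0.0))
        x = rng.standard_normal((2, 1500))
        ep = extract_epochs(x, 100.0, [100], cfg)
        # epoch stores the baseline second too; the MI window alone is 1200
        assert crop(ep, 0.0, 12.0).n_samples == 1200

    def test_baseline_window_mean_is_zero(self, rng):
        x = rng.standard_normal((3, 2000)) + 5.0
        ep = extract_epochs(x, 100.0, [500, 900], self.CFG)
        tmask = (ep.times >= -0.2) & (ep.times < 0.0)
        base = ep.data[:, :, tmask].mean(axis=2)
        assert np.allclose(base, 0.0, atol=1e-9 * np.abs(ep.data).max())

    def test_out_of_bounds_names_trial(self):
        with pytest.raises(IndexError, match="trial 1"):
            extract_epochs(np.zeros((1, 300)), 100.0, [100, 295], self.CFG)


class TestContainerIO:
    def test_lossless_round_trip(self, tmp_path, rng):
        ep = EpochSet(rng.standard_normal((5, 3, 40)).astype(np.float32),
                      rng.integers(0, 3, 5), ["C3", "Cz", "C4"], 100.0,
                      t0=-1.0, subject_id="S09")
        path = tmp_path / "e.h5"
        write_epochs(path, ep)
        back = read_epochs(path)
        assert np.array_equal(back.data.astype(np.float32), ep.data)
        assert np.array_equal(back.labels, ep.labels)
        assert back.channel_names == ep.channel_names
        assert (back.fs, back.t0, back.subject_id) == (100.0, -1.0, "S09")

    def test_missing_labels_is_format_error(self, tmp_path):
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.zeros((2, 2, 5), dtype=np.float32))
            f.attrs["fs"] = 100.0
            f.attrs["t0"] = 0.0
            f.attrs["channel_names"] = [b"C3", b"C4"]
        with pytest.raises(FormatError, match="labels"):
            read_epochs(path)

    def test_duplicate_channel_names_rejected(self, tmp_path):
        path = tmp_path / "dup.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.zeros((2, 2, 5), dtype=np.float32))
            f.create_dataset("labels", data=np.zeros(2, dtype=np.int16))
            f.attrs["fs"] = 100.0
            f.attrs["t0"] = 0.0
            f.attrs["channel_names"] = [b"C3", b"C3"]
        with pytest.raises(FormatError, match="unique"):
            read_epochs(path)

    def test_label_length_mismatch_rejected(self, tmp_path):
        path = tmp_path / "mis.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.zeros((3, 2, 5), dtype=np.float32))
            f.create_dataset("labels", data=np.zeros(2, dtype=np.int16))
            f.attrs["fs"] = 100.0
            f.attrs["t0"] = 0.0
            f.attrs["channel_names"] = [b"C3", b"C4"]
        with pytest.raises(FormatError, match="labels"):
            read_epochs(path)


def test_chain_is_deterministic(rng):
    from fnssir.epochs import preprocess_continuous

    x = rng.standard_normal((4, 14000))
    kw = dict(fs=200.0, onsets=[2000, 3500],
              cfg=PreprocessConfig(epoch_window=(0.0, 2.0),
                                   baseline_window=(-0.5, 0.0)))
    a = preprocess_continuous(x, **kw)
    b = preprocess_continuous(x, **kw)
    assert np.array_equal(a.data, b.data)
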