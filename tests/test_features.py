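"""Windowing and spectral feature extraction, checked against independent
oracles (brute-force window enumeration, naive O(n^2) DFT, direct wavelet
convolution)."""

import numpy as np
import pytest
import pywt

import ictal2d as it
from ictal2d.features import cwt_scalogram, fft_band_features, slice_record

from conftest import sinusoid_slice


def brute_force_slice_count(n_samples, fs, window_s, overlap_frac):
    """Enumerate valid start offsets directly."""
    window_samples = int(np.floor(window_s * fs))
    step_samples = max(1, int(round(window_s * (1 - overlap_frac) * fs)))
    count = 0
    start = 0
    while start + window_samples <= n_samples:
        count += 1
        start += step_samples
    return count


def naive_dft_band_features(data, fs, band, spacing=1.0):
    """O(n^2) DFT + binning oracle, sharing no code with the implementation."""
    lo, hi = band
    n = data.shape[1]
    x = data - data.mean(axis=1, keepdims=True)
    k = np.arange(n // 2 + 1)
    t = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(k, t) / n)
    mags = np.abs(x @ dft.T)
    freqs = k * fs / n
    centers = [lo + spacing * i for i in range(int(round((hi - lo) / spacing)) + 1)]
    out = np.empty((data.shape[0], len(centers)))
    for i, f in enumerate(centers):
        sel = (freqs >= f - spacing / 2) & (freqs < f + spacing / 2)
        out[:, i] = mags[:, sel].mean(axis=1)
    return out


def direct_cwt_row_means(x, fs, wavelet_name, scales):
    """Direct convolution of the scaled, sampled mother wavelet with the
    signal: the textbook CWT definition."""
    wav = pywt.ContinuousWavelet(wavelet_name)
    means = []
    for a in scales:
        # sample psi((t)/a) on the wavelet's support, at the signal's rate
        width = wav.upper_bound - wav.lower_bound
        m = max(int(np.ceil(a * width)), 3)
        t = np.linspace(wav.lower_bound, wav.upper_bound, m)
        psi = wav.wavefun(length=m)[0]
        kernel = np.conj(psi[::-1]) / np.sqrt(a)
        w = np.convolve(x, kernel, mode="same")
        means.append(np.abs(w).mean())
    return np.asarray(means)


class TestSliceRecord:
    def test_window_equal_to_record_gives_one_slice(self, bonn_like_record):
        cfg = it.WindowConfig(window_s=23.6, overlap_frac=0.5)
        assert len(slice_record(bonn_like_record, cfg)) == 1

    def test_one_second_window_half_overlap_gives_46(self, bonn_like_record):
        cfg = it.WindowConfig(window_s=1.0, overlap_frac=0.5)
        assert len(slice_record(bonn_like_record, cfg)) == 46

    def test_fully_annotated_record_labels_all_seizure(self):
        rec = it.EEGRecord(data=np.zeros((1, 1000)) + 1.0, fs=100.0,
                           annotations=[it.SeizureInterval(0.0, 10.0)])
        for window_s in (1.0, 2.5, 10.0):
            slices = slice_record(rec, it.WindowConfig(window_s=window_s))
            assert slices
            assert all(s.label == "seizure" for s in slices)

    def test_window_longer_than_record_is_an_error(self):
        rec = it.EEGRecord(data=np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError, match="does not fit"):
            slice_record(rec, it.WindowConfig(window_s=2.0))

    def test_count_matches_brute_force_enumeration(self):
        """200 random (duration, window, overlap) triples."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            fs = rng.uniform(50, 400)
            duration = rng.uniform(2.0, 60.0)
            window = rng.uniform(0.25, duration)
            overlap = rng.uniform(0.0, 0.9)
            n = int(round(duration * fs))
            rec = it.EEGRecord(data=np.zeros((1, n)), fs=fs)
            cfg = it.WindowConfig(window_s=window, overlap_frac=overlap)
            expected = brute_force_slice_count(n, fs, window, overlap)
            if expected == 0:
                with pytest.raises(ValueError):
                    slice_record(rec, cfg)
            else:
                assert len(slice_record(rec, cfg)) == expected

    def test_slice_start_times_follow_step(self, bonn_like_record):
        cfg = it.WindowConfig(window_s=2.0, overlap_frac=0.5)
        slices = slice_record(bonn_like_record, cfg)
        starts = np.array([s.t_start_s for s in slices])
        step = int(round(cfg.step_s * bonn_like_record.fs))
        expected = np.arange(len(slices)) * step / bonn_like_record.fs
        np.testing.assert_allclose(starts, expected)

    def test_labeled_duration_tracks_annotated_duration(self):
        """With label_rule 0.5, total seizure-labeled slice time matches the
        annotated seizure time to within one window length."""
        rng = np.random.default_rng(3)
        fs, total = 100.0, 60.0
        rec = it.EEGRecord(
            data=rng.normal(size=(1, int(total * fs))), fs=fs,
            annotations=[it.SeizureInterval(12.0, 31.0)],
        )
        window_s = 2.0
        slices = slice_record(rec, it.WindowConfig(window_s, overlap_frac=0.0),
                              label_rule=0.5)
        labeled = sum(window_s for s in slices if s.label == "seizure")
        assert abs(labeled - 19.0) <= window_s

    def test_partial_overlap_labeling_threshold(self):
        rec = it.EEGRecord(data=np.zeros((1, 1000)), fs=100.0,
                           annotations=[it.SeizureInterval(0.0, 5.0)])
        # the slice [4, 6) s is half-covered
        slices = slice_record(rec, it.WindowConfig(2.0, overlap_frac=0.0),
                              label_rule=0.5)
        assert [s.label for s in slices] == [
            "seizure", "seizure", "seizure", "nonseizure", "nonseizure"
        ]
        strict = slice_record(rec, it.WindowConfig(2.0, overlap_frac=0.0),
                              label_rule=1.0)
        assert [s.label for s in strict] == [
            "seizure", "seizure", "nonseizure", "nonseizure", "nonseizure"
        ]


class TestCwtScalogram:
    def test_shape_contract(self):
        slc = sinusoid_slice(10.0, fs=100.0, duration_s=1.0)
        fm = cwt_scalogram(slc, total_scale=10)
        assert fm.shape == (10, 100)
        assert fm.row_axis == "scale"
        assert fm.col_axis == "time"
        assert fm.row_labels == list(range(1, 11))

    def test_zero_signal_gives_zero_map(self):
        slc = it.Slice(data=np.zeros((1, 200)), fs=100.0, t_start_s=0.0,
                       label="nonseizure", source=("s", "r"))
        fm = cwt_scalogram(slc)
        assert np.all(fm.values == 0)

    def test_multichannel_input_redirected(self, multichannel_slice):
        with pytest.raises(ValueError, match="fft_band_features"):
            cwt_scalogram(multichannel_slice)

    def test_homogeneity(self):
        """Scaling the input by c scales every magnitude by |c|."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        base = it.Slice(data=x[None], fs=100.0, t_start_s=0.0,
                        label="nonseizure", source=("s", "r"))
        scaled = it.Slice(data=-2.5 * x[None], fs=100.0, t_start_s=0.0,
                          label="nonseizure", source=("s", "r"))
        fa = cwt_scalogram(base).values
        fb = cwt_scalogram(scaled).values
        np.testing.assert_allclose(fb, 2.5 * fa, atol=1e-10)

    def test_peak_scale_matches_direct_convolution_oracle(self):
        """A sinusoid at scale 5's center frequency peaks in row 5, and the
        direct-convolution oracle agrees on the peak scale."""
        fs, total_scale = 100.0, 10
        fc = pywt.central_frequency("cgau8")
        target_scale = 5
        freq = fc * fs / target_scale
        slc = sinusoid_slice(freq, fs=fs, duration_s=4.0)
        fm = cwt_scalogram(slc, "cgau8", total_scale)
        row_means = fm.values.mean(axis=1)
        assert int(np.argmax(row_means)) + 1 == target_scale
        oracle = direct_cwt_row_means(slc.data[0], fs, "cgau8",
                                      range(1, total_scale + 1))
        assert int(np.argmax(oracle)) + 1 == target_scale


class TestFftBandFeatures:
    def test_23_channel_band_1_23_gives_23x23(self, multichannel_slice):
        fm = fft_band_features(multichannel_slice, (1.0, 23.0))
        assert fm.shape == (23, 23)
        assert fm.row_axis == "channel"
        assert fm.col_axis == "frequency"

    def test_23_channel_band_1_46_gives_23x46(self, multichannel_slice):
        assert fft_band_features(multichannel_slice, (1.0, 46.0)).shape == (23, 46)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        slc = sinusoid_slice(10.0, fs=256.0, duration_s=1.0)
        fm = fft_band_features(slc, (1.0, 30.0))
        col = fm.values[0]
        freqs = np.asarray(fm.col_labels)
        assert freqs[np.argmax(col)] == 10.0
        far = col[np.abs(freqs - 10.0) > 1.0]
        assert col.max() >= 10 * far.max()

    def test_agrees_with_naive_dft_oracle(self):
        rng = np.random.default_rng(4)
        for n, fs in [(128, 64.0), (256, 100.0), (512, 256.0)]:
            data = rng.normal(size=(3, n))
            slc = it.Slice(data=data, fs=fs, t_start_s=0.0,
                           label="nonseizure", source=("s", "r"))
            got = fft_band_features(slc, (2.0, 20.0)).values
            want = naive_dft_band_features(data, fs, (2.0, 20.0))
            np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_window_too_short_for_spacing_names_minimum(self):
        slc = sinusoid_slice(5.0, fs=256.0, duration_s=0.5)
        with pytest.raises(ValueError, match="at least"):
            fft_band_features(slc, (2.0, 20.0), spacing=1.0)

    def test_band_above_nyquist_rejected(self):
        slc = sinusoid_slice(5.0, fs=100.0, duration_s=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            fft_band_features(slc, (1.0, 60.0))


class TestFeatureMapSerialization:
    def test_tsv_round_trip(self, tmp_path, multichannel_slice):
        from ictal2d.features import load_feature_map, save_feature_map

        fm = fft_band_features(multichannel_slice, (1.0, 23.0))
        path = tmp_path / "fm.tsv"
        save_feature_map(fm, path)
        back = load_feature_map(path)
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.row_axis == fm.row_axis
        assert back.col_labels == [float(v) for v in fm.col_labels]
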