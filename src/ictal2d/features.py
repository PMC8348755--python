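"""Sliding-window decomposition and spectral feature extraction.

A record is decomposed into fixed-length, optionally overlapping slices;
each slice is then reduced to a 2D feature map:

* single-channel slices: magnitude of the continuous wavelet transform at
  integer scales 1..total_scale (complex Gaussian ``cgau8`` mother wavelet
  by default), a scale x time scalogram;
* multichannel slices: per-channel FFT magnitudes averaged into 1 Hz-wide
  (configurable) bins over a frequency band, a channel x frequency map.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pywt

from .eeg_io import EEGRecord, NONSEIZURE, SEIZURE

DEFAULT_WAVELET = "cgau8"
DEFAULT_TOTAL_SCALE = 10


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters: length in seconds and overlap fraction."""

    window_s: float
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError(f"window_s must be positive, got {self.window_s}")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError(
                f"overlap_frac must lie in [0, 1), got {self.overlap_frac}"
            )

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap_frac)


@dataclass
class Slice:
    """One windowed segment of a record, with label and provenance."""

    data: np.ndarray  # channels x window_samples
    fs: float
    t_start_s: float
    label: str
    source: tuple[str, str]  # (subject_id, record_id)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.label not in (SEIZURE, NONSEIZURE):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def window_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class FeatureMap:
    """A 2D real feature array with axis metadata."""

    values: np.ndarray
    row_axis: str  # "scale" or "channel"
    col_axis: str  # "time" or "frequency"
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature map values must be 2D")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def slice_record(
    record: EEGRecord,
    cfg: WindowConfig,
    label_rule: float = 1.0,
) -> list[Slice]:
    """Decompose a record into sliding-window slices.

    Slice k starts at k * step_s. A slice is labeled seizure iff the
    fraction of its span covered by annotated seizure intervals is at least
    ``label_rule`` (default 1.0: the slice must lie wholly inside a
    seizure).
    """
    if not 0 <= label_rule <= 1:
        raise ValueError(f"label_rule must lie in [0, 1], got {label_rule}")
    window_samples = int(np.floor(cfg.window_s * record.fs))
    if window_samples < 1 or window_samples > record.n_samples:
        raise ValueError(
            f"window of {cfg.window_s} s ({window_samples} samples) does not "
            f"fit in a record of {record.duration_s:.3f} s"
        )
    step_samples = max(1, int(round(cfg.step_s * record.fs)))
    window_span_s = window_samples / record.fs

    slices: list[Slice] = []
    start = 0
    while start + window_samples <= record.n_samples:
        t0 = start / record.fs
        t1 = t0 + window_span_s
        covered = 0.0
        for iv in record.annotations:
            covered += max(0.0, min(t1, iv.end_s) - max(t0, iv.start_s))
        frac = covered / window_span_s
        label = SEIZURE if frac >= label_rule - 1e-9 else NONSEIZURE
        slices.append(
            Slice(
                data=record.data[:, start:start + window_samples].copy(),
                fs=record.fs,
                t_start_s=t0,
                label=label,
                source=(record.subject_id, record.record_id),
            )
        )
        start += step_samples
    return slices


def cwt_scalogram(
    slc: Slice,
    wavelet_name: str = DEFAULT_WAVELET,
    total_scale: int = DEFAULT_TOTAL_SCALE,
) -> FeatureMap:
    """Continuous-wavelet-transform magnitude at integer scales 1..total_scale.

    Single-channel slices only; multichannel data should go through
    :func:`fft_band_features` instead.
    """
    if slc.n_channels != 1:
        raise ValueError(
            f"cwt_scalogram expects a single-channel slice, got "
            f"{slc.n_channels} channels; use fft_band_features for "
            "multichannel data"
        )
    if total_scale < 1:
        raise ValueError("total_scale must be >= 1")
    scales = np.arange(1, total_scale + 1)
    coeffs, _ = pywt.cwt(slc.data[0], scales, wavelet_name,
                         sampling_period=1.0 / slc.fs)
    times = slc.t_start_s + np.arange(slc.window_samples) / slc.fs
    return FeatureMap(
        values=np.abs(coeffs),
        row_axis="scale",
        col_axis="time",
        row_labels=list(scales),
        col_labels=list(times),
    )


def fft_band_features(
    slc: Slice,
    band: tuple[float, float],
    spacing: float = 1.0,
) -> FeatureMap:
    """Per-channel FFT magnitudes binned over a frequency band.

    The per-channel mean is removed, the DFT magnitude computed, and for
    each center frequency f in {lo, lo+spacing, ..., hi} the magnitudes of
    DFT bins with frequency in [f - spacing/2, f + spacing/2) are averaged.
    Output is channels x n_centers; e.g. a 23-channel slice over 1-23 Hz
    gives a 23 x 23 map, over 1-46 Hz a 23 x 46 map.
    """
    lo, hi = band
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not (spacing <= lo <= hi):
        raise ValueError(f"band must satisfy spacing <= lo <= hi, got {band}")
    if hi >= slc.fs / 2:
        raise ValueError(
            f"band upper edge {hi} Hz must be below Nyquist ({slc.fs / 2} Hz)"
        )
    n = slc.window_samples
    df = slc.fs / n  # DFT bin width
    if df > spacing:
        min_window = 1.0 / spacing
        raise ValueError(
            f"window of {n / slc.fs:.3f} s gives {df:.3f} Hz resolution, too "
            f"coarse for {spacing} Hz bins; use a window of at least "
            f"{min_window:.3f} s"
        )
    centers = lo + spacing * np.arange(int(round((hi - lo) / spacing)) + 1)
    x = slc.data - slc.data.mean(axis=1, keepdims=True)
    mags = np.abs(np.fft.rfft(x, axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / slc.fs)

    values = np.empty((slc.n_channels, centers.size))
    for i, f in enumerate(centers):
        in_bin = (freqs >= f - spacing / 2) & (freqs < f + spacing / 2)
        if not np.any(in_bin):  # unreachable once df <= spacing, kept as guard
            raise ValueError(f"no DFT bins fall in the {f} Hz aggregation bin")
        values[:, i] = mags[:, in_bin].mean(axis=1)
    return FeatureMap(
        values=values,
        row_axis="channel",
        col_axis="frequency",
        row_labels=list(range(slc.n_channels)),
        col_labels=list(centers),
    )


def save_feature_map(fm: FeatureMap, path: str | os.PathLike) -> None:
    """Write a feature map as TSV with a JSON sidecar holding axis metadata."""
    np.savetxt(path, fm.values, delimiter="\t")
    sidecar = {
        "row_axis": fm.row_axis,
        "col_axis": fm.col_axis,
        "row_labels": [float(v) for v in fm.row_labels],
        "col_labels": [float(v) for v in fm.col_labels],
    }
    with open(f"{os.fspath(path)}.json", "w") as fh:
        json.dump(sidecar, fh)


def load_feature_map(path: str | os.PathLike) -> FeatureMap:
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    with open(f"{os.fspath(path)}.json") as fh:
        sidecar = json.load(fh)
    return FeatureMap(values=values, **sidecar)
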