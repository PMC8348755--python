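"""EEG record I/O and synthetic fixture generation.

Two on-disk dialects are supported:

* single-channel ASCII clips (one numeric sample per line, the format used
  by the classic intracranial epilepsy clip collections, nominally sampled
  at 173.61 Hz), and
* multichannel scalp EEG in European Data Format (EDF) with an optional
  plain-text seizure annotation file in the ``Seizure Start Time: N
  seconds`` summary dialect used by scalp-EEG seizure corpora.

A seeded synthetic generator produces records in either shape so the whole
pipeline is exercisable without any dataset download: interictal records
are 1/f-like colored noise; ictal records add a high-amplitude rhythmic
oscillation in a configurable band.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

#: Nominal sampling rate (Hz) of the single-channel ASCII clip dialect.
BONN_FS = 173.61

SEIZURE = "seizure"
NONSEIZURE = "nonseizure"


class AliasingError(ValueError):
    """Requested oscillation band extends beyond the Nyquist frequency."""


@dataclass(frozen=True)
class SeizureInterval:
    """A seizure annotation, in seconds from record start."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecord:
    """A multichannel EEG recording with seizure annotations.

    ``data`` is channels x samples in microvolts; ``fs`` is the sampling
    rate in Hz.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[SeizureInterval] = field(default_factory=list)
    subject_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n_ch, n_samp = self.data.shape
        if n_samp < 1:
            raise ValueError("record must contain at least one sample")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        for iv in self.annotations:
            if iv.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{iv.start_s}, {iv.end_s}] s exceeds record "
                    f"duration {self.duration_s:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic EEG cohort.

    Defaults emulate a small scalp-EEG seizure corpus: five subjects, 23
    channels at 256 Hz, with ictal activity concentrated in the alpha band
    at four times the background RMS.
    """

    n_subjects: int = 5
    records_per_subject: int = 4
    channels: int = 23
    fs: float = 256.0
    duration_s: float = 30.0
    ictal_band: tuple[float, float] = (8.0, 12.0)
    ictal_amplitude_ratio: float = 4.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ictal_band
        if not lo < hi:
            raise ValueError(f"ictal_band lo must be < hi, got {self.ictal_band}")
        if hi >= self.fs / 2:
            raise AliasingError(
                f"ictal_band upper edge {hi} Hz is at or above Nyquist "
                f"({self.fs / 2} Hz)"
            )
        if self.ictal_amplitude_ratio < 0:
            raise ValueError("ictal_amplitude_ratio must be >= 0")


# ---------------------------------------------------------------------------
# Single-channel ASCII dialect
# ---------------------------------------------------------------------------

def read_bonn_ascii(path: str | os.PathLike, fs: float = BONN_FS) -> EEGRecord:
    """Read a single-channel ASCII clip (one numeric sample per line).

    The dialect carries no header, so ``fs`` defaults to the collection's
    nominal 173.61 Hz but may be overridden.
    """
    samples: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric sample {text!r} on line {lineno}"
                ) from None
    if not samples:
        raise ValueError(f"{path}: file contains no samples")
    rid = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return EEGRecord(
        data=np.asarray(samples, dtype=np.float64)[None, :],
        fs=fs,
        record_id=rid,
    )


def write_bonn_ascii(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write a 1-channel record in the ASCII clip dialect.

    Integral samples are written as integers (matching the dialect);
    non-integral samples are written with full float repr so a round trip
    is bitwise exact.
    """
    if record.n_channels != 1:
        raise ValueError("ASCII clip dialect is single-channel")
    x = record.data[0]
    with open(path, "w") as fh:
        if np.all(x == np.round(x)):
            fh.writelines(f"{int(v)}\n" for v in x)
        else:
            fh.writelines(f"{float(v)!r}\n" for v in x)


# ---------------------------------------------------------------------------
# EDF dialect
# ---------------------------------------------------------------------------

def read_edf(
    path: str | os.PathLike,
    annotation_path: str | os.PathLike | None = None,
) -> EEGRecord:
    """Read a multichannel EDF record, optionally attaching seizure intervals
    parsed from a summary-dialect annotation file."""
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for bad headers
        raise ValueError(f"{path}: not a readable EDF file ({exc})") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    record = EEGRecord(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        record_id=os.path.splitext(os.path.basename(os.fspath(path)))[0],
    )
    if annotation_path is not None:
        intervals = parse_seizure_annotations(
            annotation_path, record_name=os.path.basename(os.fspath(path))
        )
        for iv in intervals:
            if iv.end_s > record.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{iv.start_s}, {iv.end_s}] s lies beyond the "
                    f"{record.duration_s:.3f} s record {record.record_id}"
                )
        record.annotations = intervals
    return record


_START_RE = re.compile(r"Seizure(?:\s+\d+)?\s+Start\s+Time:\s*([\d.]+)", re.I)
_END_RE = re.compile(r"Seizure(?:\s+\d+)?\s+End\s+Time:\s*([\d.]+)", re.I)
_FILE_RE = re.compile(r"File\s+Name:\s*(\S+)", re.I)


def parse_seizure_annotations(
    path: str | os.PathLike, record_name: str | None = None
) -> list[SeizureInterval]:
    """Parse ``Seizure Start/End Time`` lines from a summary-dialect file.

    If the file contains ``File Name:`` blocks and ``record_name`` is given,
    only the block for that record is used; otherwise every start/end pair
    in the file is returned. All other summary content is ignored.
    """
    with open(path) as fh:
        text = fh.read()
    blocks: list[tuple[str | None, str]] = []
    file_matches = list(_FILE_RE.finditer(text))
    if file_matches:
        for i, m in enumerate(file_matches):
            end = file_matches[i + 1].start() if i + 1 < len(file_matches) else len(text)
            blocks.append((m.group(1), text[m.end():end]))
    else:
        blocks.append((None, text))

    intervals: list[SeizureInterval] = []
    for name, body in blocks:
        if record_name is not None and name is not None and name != record_name:
            continue
        starts = [float(m.group(1)) for m in _START_RE.finditer(body)]
        ends = [float(m.group(1)) for m in _END_RE.finditer(body)]
        if len(starts) != len(ends):
            raise ValueError(
                f"{path}: {len(starts)} seizure start times but {len(ends)} "
                "end times"
            )
        intervals.extend(SeizureInterval(s, e) for s, e in zip(starts, ends))
    return intervals


def write_edf(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write a record as a minimal 16-bit EDF file.

    Emits one data record per second (so ``fs`` must be integral), physical
    units microvolts, digital range the full int16 span. Values are
    quantized to 16 bits, as the format requires.
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integral sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s data record
    n_ch, n_samp = record.data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr), dtype=np.float64)
    padded[:, :n_samp] = record.data

    phys_min = np.floor(padded.min(axis=1))
    phys_max = np.ceil(padded.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {record.subject_id or 'X'}", 80),
        pad(f"Startdate X X X {record.record_id or 'X'}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    sig_header = b"".join([
        b"".join(pad(name, 16) for name in record.channel_names),
        b"".join(pad("EEG", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{phys_min[c]:g}", 8) for c in range(n_ch)),
        b"".join(pad(f"{phys_max[c]:g}", 8) for c in range(n_ch)),
        b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())


def write_annotation_summary(
    entries: list[tuple[str, list[SeizureInterval]]], path: str | os.PathLike
) -> None:
    """Write a summary-dialect annotation file: one block per record name."""
    with open(path, "w") as fh:
        for name, intervals in entries:
            fh.write(f"File Name: {name}\n")
            fh.write(f"Number of Seizures in File: {len(intervals)}\n")
            for i, iv in enumerate(intervals, start=1):
                tag = f"Seizure {i} " if len(intervals) > 1 else "Seizure "
                fh.write(f"{tag}Start Time: {iv.start_s:g} seconds\n")
                fh.write(f"{tag}End Time: {iv.end_s:g} seconds\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

def _colored_noise(rng: np.random.Generator, n_ch: int, n: int, exponent: float,
                   fs: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f^-exponent,
    unit RMS per channel."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = amp * (
        rng.standard_normal((n_ch, freqs.size))
        + 1j * rng.standard_normal((n_ch, freqs.size))
    )
    x = np.fft.irfft(spectrum, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def generate_synthetic(
    spec: SyntheticSpec,
    state: str,
    subject: int = 0,
    record: int = 0,
) -> EEGRecord:
    """Generate one synthetic EEG record.

    ``state`` is ``"ictal"`` or ``"interictal"``. The background noise
    stream is keyed by (seed, subject, record) only, so the ictal record is
    the interictal record plus the oscillation — classes differ exactly by
    the rhythmic component the downstream spectral features must detect.
    Ictal records carry one seizure interval covering the full duration.
    """
    if state not in ("ictal", "interictal"):
        raise ValueError(f"state must be 'ictal' or 'interictal', got {state!r}")
    n = int(round(spec.duration_s * spec.fs))
    bg_rng = np.random.default_rng([spec.seed, subject, record, 0x0BAC])
    x = 10.0 * _colored_noise(bg_rng, spec.channels, n, spec.noise_exponent, spec.fs)

    annotations: list[SeizureInterval] = []
    if state == "ictal":
        osc_rng = np.random.default_rng([spec.seed, subject, record, 0x1C7A])
        lo, hi = spec.ictal_band
        f0 = osc_rng.uniform(lo, hi)
        phases = osc_rng.uniform(0, 2 * np.pi, size=spec.channels)
        t = np.arange(n) / spec.fs
        # rhythmic discharge: one dominant frequency, 20% AM at 0.5 Hz
        carrier = np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None])
        envelope = 1.0 + 0.2 * np.sin(2 * np.pi * 0.5 * t)
        osc = carrier * envelope[None, :]
        bg_rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
        osc_rms = np.sqrt(np.mean(osc**2, axis=1, keepdims=True))
        x = x + osc * (spec.ictal_amplitude_ratio * bg_rms / osc_rms)
        annotations.append(SeizureInterval(0.0, n / spec.fs))

    return EEGRecord(
        data=x,
        fs=spec.fs,
        annotations=annotations,
        subject_id=f"S{subject:02d}",
        record_id=f"S{subject:02d}r{record:02d}{'i' if state == 'ictal' else 'n'}",
    )


def generate_cohort(spec: SyntheticSpec) -> list[EEGRecord]:
    """Generate the full cohort: for every subject, ``records_per_subject``
    records alternating interictal/ictal (half each, ictal first)."""
    records = []
    for s in range(spec.n_subjects):
        for r in range(spec.records_per_subject):
            state = "ictal" if r % 2 == 0 else "interictal"
            records.append(generate_synthetic(spec, state, subject=s, record=r))
    return records
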