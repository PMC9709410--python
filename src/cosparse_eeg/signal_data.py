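"""Synthetic EEG-like signal generation, ASCII reading, segmentation and ICA.

The synthetic generator emulates two labelled classes of single-channel EEG:
a shared oscillatory background (a sum of sinusoids plus Gaussian white noise,
with an optional 1/f "pink" component) and, in the positive class only, randomly
placed high-amplitude spike-wave bursts — the classical signature of ictal EEG.
All parameters live in :class:`SyntheticSpec` so tests control class
separability explicitly.

The ASCII reader handles the one-integer-per-line dialect used by classic
single-channel epilepsy recordings (173.61 Hz, 4097 samples per record).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sampling rate (Hz) of the single-channel epilepsy ASCII dialect.
BONN_FS = 173.61
#: Samples per record in that dialect.
BONN_RECORD_LENGTH = 4097
#: Conventional number of chunks each record is divided into.
BONN_N_CHUNKS = 23


class ParameterError(ValueError):
    """A spec/config field failed validation; the message names the field."""


@dataclass(frozen=True)
class SignalRecord:
    """One labelled single-channel time series."""

    samples: np.ndarray
    fs: float
    label: str
    record_id: str

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ParameterError("samples: must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples: contains non-finite values")
        if not self.fs > 0:
            raise ParameterError(f"fs: must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class SegmentedDataset:
    """Fixed-length chunks cut from one or more records.

    ``provenance`` keeps ``(record_id, chunk_index)`` per row so grouped
    cross-validation can avoid leaking chunks of one record across folds.
    """

    segments: np.ndarray          # (n_segments, segment_length)
    labels: np.ndarray            # (n_segments,) str
    fs: float
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        segments = np.asarray(self.segments, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "labels", labels)
        if segments.ndim != 2:
            raise ParameterError("segments: expected a 2-D matrix")
        if labels.shape[0] != segments.shape[0]:
            raise ParameterError("labels: length must equal n_segments")
        if len(self.provenance) != segments.shape[0]:
            raise ParameterError("provenance: length must equal n_segments")

    @property
    def n_segments(self) -> int:
        return int(self.segments.shape[0])

    @property
    def record_ids(self) -> np.ndarray:
        """Source record id per segment (the grouping key for CV)."""
        return np.asarray([rid for rid, _ in self.provenance])


def concatenate_datasets(datasets: Sequence[SegmentedDataset]) -> SegmentedDataset:
    """Stack several segmented datasets (same fs and segment length)."""
    if not datasets:
        raise ParameterError("datasets: empty")
    fs = datasets[0].fs
    width = datasets[0].segments.shape[1]
    for d in datasets:
        if d.fs != fs or d.segments.shape[1] != width:
            raise ParameterError("datasets: mismatched fs or segment length")
    return SegmentedDataset(
        segments=np.vstack([d.segments for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        fs=fs,
        provenance=[p for d in datasets for p in d.provenance],
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating conditions for the two-class synthetic signals.

    background
        list of (frequency Hz, amplitude) sinusoids shared by both classes.
    noise_std
        standard deviation of the Gaussian white background noise.
    pink_std
        optional 1/f component amplitude (0 disables it).
    burst_rate / burst_duration / burst_gain / burst_freq
        Poisson rate (events/s), event duration (s), amplitude of each
        spike-wave burst as a multiple of the background noise std, and the
        burst oscillation frequency (Hz).  Bursts are added to the positive
        class only.  The defaults (3 events/s of ~0.33 s at 3 Hz) emulate the
        near-continuous 3 Hz spike-wave trains of ictal EEG, so essentially
        every chunk of a positive record carries burst energy.
    """

    n_records_per_class: int = 40
    record_length: int = BONN_RECORD_LENGTH
    fs: float = BONN_FS
    background: tuple[tuple[float, float], ...] = ((10.0, 1.0), (2.0, 0.5))
    noise_std: float = 1.0
    pink_std: float = 0.0
    burst_rate: float = 3.0
    burst_duration: float = 0.33
    burst_gain: float = 5.0
    burst_freq: float = 3.0
    seed: int = 0
    positive_label: str = "ictal"
    negative_label: str = "interictal"

    def __post_init__(self) -> None:
        if self.n_records_per_class < 1:
            raise ParameterError("n_records_per_class: must be >= 1")
        if self.record_length < 2:
            raise ParameterError("record_length: must be >= 2")
        if not self.fs > 0:
            raise ParameterError(f"fs: must be > 0, got {self.fs}")
        for f, a in self.background:
            if f < 0 or a < 0:
                raise ParameterError("background: frequencies/amplitudes must be >= 0")
        for name in ("noise_std", "pink_std", "burst_rate", "burst_duration",
                     "burst_gain", "burst_freq"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: must be >= 0")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n)
    std = pink.std()
    return pink / std if std > 0 else pink


def generate_synthetic(spec: SyntheticSpec) -> list[SignalRecord]:
    """Generate ``2 * n_records_per_class`` labelled records.

    Bit-reproducible for identical ``spec`` (including ``seed``).  Burst
    amplitude is ``burst_gain * noise_std`` (or ``burst_gain`` alone when the
    spec is noise-free) so the gain is expressed relative to the background.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.record_length) / spec.fs
    burst_amp = spec.burst_gain * (spec.noise_std if spec.noise_std > 0 else 1.0)
    records: list[SignalRecord] = []
    for label in (spec.negative_label, spec.positive_label):
        positive = label == spec.positive_label
        for i in range(spec.n_records_per_class):
            x = np.zeros(spec.record_length)
            for freq, amp in spec.background:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                x += amp * np.sin(2.0 * np.pi * freq * t + phase)
            if spec.noise_std > 0:
                x += spec.noise_std * rng.standard_normal(spec.record_length)
            if spec.pink_std > 0:
                x += spec.pink_std * _pink_noise(rng, spec.record_length)
            if positive:
                x = _add_bursts(rng, x, t, spec, burst_amp)
            records.append(
                SignalRecord(samples=x, fs=spec.fs, label=label,
                             record_id=f"{label}-{i:03d}")
            )
    return records


def _add_bursts(rng: np.random.Generator, x: np.ndarray, t: np.ndarray,
                spec: SyntheticSpec, burst_amp: float) -> np.ndarray:
    duration_s = t[-1] if t.size > 1 else 0.0
    n_bursts = rng.poisson(spec.burst_rate * duration_s) if duration_s > 0 else 0
    burst_len = max(int(round(spec.burst_duration * spec.fs)), 1)
    win = np.hanning(burst_len + 2)[1:-1]  # strictly positive taper
    tb = np.arange(burst_len) / spec.fs
    for _ in range(n_bursts):
        start = rng.integers(0, max(len(x) - burst_len, 1))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(2.0 * np.pi * spec.burst_freq * tb + phase)
        # sharpen into a spike-wave by mixing in a clipped harmonic
        wave = 0.7 * wave + 0.3 * np.sign(wave) * np.abs(wave) ** 0.25
        stop = min(start + burst_len, len(x))
        x[start:stop] += burst_amp * (win * wave)[: stop - start]
    return x


def read_ascii_signal(path, fs: float, label: str) -> SignalRecord:
    """Read a one-numeric-value-per-line ASCII signal file.

    Blank lines are skipped; any non-numeric line raises with its 1-based
    line number.
    """
    values: list[float] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {stripped!r} at line {lineno}"
                ) from exc
    if not values:
        raise ValueError(f"{path}: file contains no numeric values")
    import os

    record_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SignalRecord(samples=np.asarray(values), fs=fs, label=label,
                        record_id=record_id)


def segment_signal(record: SignalRecord, n_chunks: int) -> SegmentedDataset:
    """Cut a record into ``n_chunks`` contiguous equal-length chunks.

    Chunk length is ``floor(len(record) / n_chunks)``; trailing remainder
    samples are discarded.  All chunks inherit the record's label.
    """
    n = len(record)
    if n_chunks < 1:
        raise ParameterError("n_chunks: must be >= 1")
    if n_chunks > n:
        raise ParameterError(
            f"n_chunks: {n_chunks} exceeds record length {n}"
        )
    chunk_len = n // n_chunks
    segs = record.samples[: n_chunks * chunk_len].reshape(n_chunks, chunk_len)
    return SegmentedDataset(
        segments=segs,
        labels=np.asarray([record.label] * n_chunks),
        fs=record.fs,
        provenance=[(record.record_id, i) for i in range(n_chunks)],
    )


def segment_records(records: Sequence[SignalRecord], n_chunks: int) -> SegmentedDataset:
    """Segment many records and stack the results."""
    return concatenate_datasets([segment_signal(r, n_chunks) for r in records])


def preprocess_ica(data: np.ndarray, n_components: int | None = None,
                   seed: int = 0) -> np.ndarray:
    """Reconstruct a multichannel signal matrix from its independent components.

    ``data`` is (n_channels, n_samples).  With ``n_components == n_channels``
    and no component rejection this is a round trip.  Single-channel input is
    a documented no-op (ICA is undefined there): the input is returned with a
    warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ParameterError("data: expected (n_channels, n_samples)")
    n_channels = data.shape[0]
    if n_channels < 2:
        warnings.warn("ICA undefined for single-channel input; returning input "
                      "unchanged", UserWarning, stacklevel=2)
        logger.warning("preprocess_ica: single-channel input, no-op")
        return data.copy()
    if n_components is None:
        n_components = n_channels
    if n_components > n_channels:
        raise ParameterError("n_components: cannot exceed n_channels")

    from sklearn.decomposition import FastICA

    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000)
    sources = ica.fit_transform(data.T)        # (n_samples, n_components)
    reconstructed = ica.inverse_transform(sources).T
    return reconstructed


def unmix_ica(data: np.ndarray, n_components: int | None = None,
              seed: int = 0) -> np.ndarray:
    """Return the estimated independent sources, (n_components, n_samples)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ParameterError("data: need >= 2 channels to unmix")
    if n_components is None:
        n_components = data.shape[0]
    from sklearn.decomposition import FastICA

    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000)
    return ica.fit_transform(data.T).T
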