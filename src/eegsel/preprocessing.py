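"""Continuous-recording preprocessing: baseline correction, zero-phase
band-pass filtering, epoch segmentation, amplitude-based artifact rejection
and random epoch subsampling."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import signal

from .montage import CHANNELS_32


class PreprocessError(ValueError):
    """Raised when an input violates a preprocessing precondition."""


class InsufficientCleanEpochsError(PreprocessError):
    """Raised when fewer artifact-free epochs survive than requested."""


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    ``filter_order`` is the Butterworth *design* order; the filter is applied
    forward and backward (zero net phase), doubling the effective magnitude
    order. Set ``filter_order=3`` for an effective 6th-order magnitude
    response.
    """

    band: Tuple[float, float] = (0.5, 50.0)
    filter_order: int = 6
    epoch_seconds: float = 5.0
    reject_threshold_uv: float = 75.0
    epochs_per_subject: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.epochs_per_subject < 1:
            raise ValueError("epochs_per_subject must be >= 1")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")


@dataclass
class EpochSet:
    """One subject's preprocessed EEG: epochs x channels x samples."""

    subject_id: str
    group: str  # "MCI" or "HC"
    data: np.ndarray
    fs: float
    channel_labels: Sequence[str] = CHANNELS_32

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.group not in ("MCI", "HC"):
            raise ValueError(f"group must be 'MCI' or 'HC', got {self.group!r}")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in data of {self.subject_id!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def design_bandpass(fs: float, band: Tuple[float, float], order: int) -> np.ndarray:
    """Butterworth band-pass as second-order sections."""
    low, high = band
    if fs <= 2.0 * high:
        raise PreprocessError(
            f"sampling rate {fs} Hz too low for band up to {high} Hz")
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def preprocess_continuous(
    raw: np.ndarray, fs: float, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Baseline-correct (per-channel mean subtraction) then zero-phase
    band-pass filter a channels x samples recording."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise PreprocessError("raw must be channels x samples")
    if not np.all(np.isfinite(raw)):
        raise PreprocessError("raw recording contains non-finite values")
    sos = design_bandpass(fs, params.band, params.filter_order)
    centered = raw - raw.mean(axis=-1, keepdims=True)
    return signal.sosfiltfilt(sos, centered, axis=-1)


def segment_epochs(filtered: np.ndarray, fs: float, epoch_seconds: float) -> np.ndarray:
    """Cut a channels x samples array into non-overlapping epochs.

    Returns epochs x channels x samples; the trailing remainder is dropped.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 2:
        raise PreprocessError("input must be channels x samples")
    epoch_len = int(round(fs * epoch_seconds))
    n_channels, n_samples = filtered.shape
    n_epochs = n_samples // epoch_len
    if n_epochs < 1:
        raise PreprocessError(
            f"recording of {n_samples} samples shorter than one "
            f"{epoch_len}-sample epoch")
    trimmed = filtered[:, : n_epochs * epoch_len]
    return trimmed.reshape(n_channels, n_epochs, epoch_len).transpose(1, 0, 2)


def reject_epochs(epochs: np.ndarray, threshold_uv: float) -> np.ndarray:
    """Boolean mask of epochs whose max |amplitude| on every channel is
    within the threshold (any-channel exceedance rejects the epoch)."""
    peak = np.abs(epochs).max(axis=(1, 2))
    return peak <= threshold_uv


def reject_and_subsample(
    epochs: np.ndarray,
    params: PreprocessParams = PreprocessParams(),
    subject_id: str = "<unknown>",
) -> np.ndarray:
    """Drop epochs exceeding the amplitude threshold, then keep exactly
    ``epochs_per_subject`` epochs chosen uniformly at random (seeded).

    The retained epochs are returned in their original temporal order, so a
    fixed seed gives a fully deterministic result.
    """
    epochs = np.asarray(epochs, dtype=float)
    keep = reject_epochs(epochs, params.reject_threshold_uv)
    clean_idx = np.flatnonzero(keep)
    n_wanted = params.epochs_per_subject
    if clean_idx.size < n_wanted:
        raise InsufficientCleanEpochsError(
            f"subject {subject_id!r}: only {clean_idx.size} clean epochs "
            f"survive the {params.reject_threshold_uv} uV threshold, "
            f"need {n_wanted}")
    rng = np.random.default_rng(params.rng_seed)
    chosen = rng.choice(clean_idx, size=n_wanted, replace=False)
    return epochs[np.sort(chosen)]


def preprocess_subject(
    raw: np.ndarray,
    fs: float,
    subject_id: str,
    group: str,
    channel_labels: Sequence[str] = CHANNELS_32,
    params: PreprocessParams = PreprocessParams(),
) -> EpochSet:
    """Full chain: filter -> segment -> reject/subsample -> EpochSet."""
    filtered = preprocess_continuous(raw, fs, params)
    epochs = segment_epochs(filtered, fs, params.epoch_seconds)
    selected = reject_and_subsample(epochs, params, subject_id=subject_id)
    return EpochSet(subject_id=subject_id, group=group, data=selected,
                    fs=fs, channel_labels=tuple(channel_labels))
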