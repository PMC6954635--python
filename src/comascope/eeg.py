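"""EEG feature extraction: channel harmonization, epoching, spectrograms.

Recordings from the two headsets are padded to a canonical 15-channel
layout (zero placeholder signals for absent electrodes) so that one
network architecture serves both devices.  The synchronized session is cut
into non-overlapping 12-s epochs, and each epoch's channels are turned
into short-time power spectra (FFT size 256, 90% overlap, Tukey window
with shape parameter 0.25 — the defaults of ``scipy.signal.spectrogram``'s
window).  Each channel's spectrogram is finally z-scored over all its
frequency-time cells; placeholder channels stay identically zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .channels import CANONICAL_15
from .io import RawEEGRecording, SessionBundle

__all__ = [
    "HarmonizedEEG",
    "EpochPair",
    "SpectrogramTensor",
    "harmonize_channels",
    "cut_epochs",
    "compute_spectrogram",
    "standardize_spectrogram",
]

EPOCH_LENGTH_S = 12.0


@dataclass
class HarmonizedEEG:
    """EEG padded to the canonical 15-channel layout."""

    samples: np.ndarray  # 15 x time
    channel_labels: tuple[str, ...]
    placeholder_mask: np.ndarray  # True where the channel is a zero placeholder
    headset: int
    sampling_rate: float = 128.0
    start_time: float = 0.0
    participant_id: str = ""
    session_label: str = ""

    @property
    def time_range(self) -> tuple[float, float]:
        return (
            self.start_time,
            self.start_time + self.samples.shape[1] / self.sampling_rate,
        )


def harmonize_channels(eeg: RawEEGRecording) -> HarmonizedEEG:
    """Pad a 5- or 14-channel recording to the canonical 15-channel union.

    Original channels are copied into their canonical slots; electrodes the
    headset lacks become zero-filled placeholder rows (10 for the
    5-electrode headset, 1 — Pz — for the 14-electrode one).
    """
    n_time = eeg.samples.shape[1]
    out = np.zeros((len(CANONICAL_15), n_time))
    mask = np.ones(len(CANONICAL_15), dtype=bool)
    index = {c: i for i, c in enumerate(CANONICAL_15)}
    for row, label in enumerate(eeg.channel_labels):
        if label not in index:
            raise ValueError(f"unknown electrode label {label!r}")
        out[index[label]] = eeg.samples[row]
        mask[index[label]] = False
    return HarmonizedEEG(
        samples=out,
        channel_labels=CANONICAL_15,
        placeholder_mask=mask,
        headset=eeg.headset,
        sampling_rate=eeg.sampling_rate,
        start_time=eeg.start_time,
        participant_id=eeg.participant_id,
        session_label=eeg.session_label,
    )


@dataclass
class EpochPair:
    """One aligned 12-s EEG epoch and its gaze samples, with provenance."""

    eeg: np.ndarray  # 15 x (epoch_length * fs)
    gaze_t: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    start: float
    end: float
    epoch_index: int
    headset: int
    participant_id: str = ""
    session_label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def epoch_id(self) -> str:
        return (
            f"{self.participant_id or 'NA'}_{self.session_label or 'NA'}_"
            f"{self.headset}_{self.epoch_index:04d}"
        )


def cut_epochs(bundle: SessionBundle, epoch_length: float = EPOCH_LENGTH_S) -> list[EpochPair]:
    """Partition the session overlap into non-overlapping fixed-length epochs.

    Consecutive windows start at the overlap's left edge; the trailing
    remainder shorter than ``epoch_length`` is discarded.  Gaze samples are
    assigned by half-open window membership ``[start, end)`` so the
    partition is exact.  The EEG is harmonized to 15 channels if it is not
    already.
    """
    eeg = bundle.eeg
    harmonized = eeg if isinstance(eeg, HarmonizedEEG) else harmonize_channels(eeg)
    fs = harmonized.sampling_rate
    lo, hi = bundle.overlap
    n_epochs = int(np.floor((hi - lo) / epoch_length + 1e-9))
    if n_epochs == 0:
        warnings.warn(
            f"overlap window of {hi - lo:.3f} s shorter than one "
            f"{epoch_length:.0f}-s epoch; no epochs produced",
            stacklevel=2,
        )
        return []
    samples_per_epoch = int(round(epoch_length * fs))
    gaze = bundle.gaze
    pairs: list[EpochPair] = []
    for k in range(n_epochs):
        start = lo + k * epoch_length
        end = start + epoch_length
        i0 = int(round((start - harmonized.start_time) * fs))
        seg = harmonized.samples[:, i0 : i0 + samples_per_epoch]
        in_win = (gaze.timestamps >= start) & (gaze.timestamps < end)
        pairs.append(
            EpochPair(
                eeg=seg,
                gaze_t=gaze.timestamps[in_win],
                gaze_x=gaze.x[in_win],
                gaze_y=gaze.y[in_win],
                start=start,
                end=end,
                epoch_index=k,
                headset=harmonized.headset,
                participant_id=harmonized.participant_id,
                session_label=harmonized.session_label,
            )
        )
    return pairs


@dataclass
class SpectrogramTensor:
    """Per-channel time-frequency power representation of one EEG epoch."""

    values: np.ndarray  # channels x frequency bins x time frames
    frequency_axis: np.ndarray  # Hz
    time_axis: np.ndarray  # seconds
    standardized: bool = False


def compute_spectrogram(
    epoch_samples: np.ndarray,
    sampling_rate: float = 128.0,
    fft_size: int = 256,
    overlap: float = 0.9,
    tukey_alpha: float = 0.25,
    log_power: bool = False,
) -> SpectrogramTensor:
    """Short-time power spectra of each channel of one epoch.

    ``noverlap = floor(overlap * fft_size)`` (230 for the defaults), giving
    a hop of 26 samples and, for a 1536-sample epoch, 129 frequency bins by
    50 time frames.  Power spectral density mode; an optional log10
    transform (with a small floor) can be applied before standardization.
    """
    epoch_samples = np.atleast_2d(np.asarray(epoch_samples, dtype=float))
    if epoch_samples.shape[1] < fft_size:
        raise ValueError(
            f"epoch of {epoch_samples.shape[1]} samples shorter than FFT size {fft_size}"
        )
    noverlap = int(np.floor(overlap * fft_size))
    f, t, sxx = sps.spectrogram(
        epoch_samples,
        fs=sampling_rate,
        window=("tukey", tukey_alpha),
        nperseg=fft_size,
        noverlap=noverlap,
        axis=-1,
    )
    if log_power:
        sxx = np.log10(sxx + 1e-12)
    return SpectrogramTensor(values=sxx, frequency_axis=f, time_axis=t)


def standardize_spectrogram(s: SpectrogramTensor, ddof: int = 0) -> SpectrogramTensor:
    """Z-score each channel's spectrogram over all its (f, t) cells.

    Uses the population standard deviation by default (``ddof=0``).
    Channels with zero variance — the zero placeholder channels in
    particular — map to all zeros instead of dividing by zero, which keeps
    them neutral for the network.  The operation is idempotent.
    """
    v = s.values
    mean = v.mean(axis=(-2, -1), keepdims=True)
    std = v.std(axis=(-2, -1), ddof=ddof, keepdims=True)
    out = np.where(std > 0, (v - mean) / np.where(std > 0, std, 1.0), 0.0)
    return replace(s, values=out, standardized=True)
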