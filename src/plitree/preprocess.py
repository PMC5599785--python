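"""Re-referencing, band-pass filtering, epoching and artifact screening.

The processing chain mirrors a conventional resting-state EEG protocol:
re-reference to a pair of mastoid channels, zero-phase band-pass filter,
cut into fixed-length non-overlapping epochs, then keep the first *k*
epochs whose per-channel peak-to-peak amplitude stays under a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "Recording",
    "EpochSet",
    "rereference",
    "bandpass",
    "epoch",
    "reject_artifacts",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-power corner frequencies in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"low={self.low}, high={self.high}"
            )

    def validate_against(self, fs: float) -> None:
        """Raise if the band is not strictly below the Nyquist frequency."""
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: upper edge {self.high} Hz >= Nyquist "
                f"({fs / 2} Hz at fs={fs})"
            )


#: Standard clinical band grid: delta, theta, alpha, beta.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 25.0),
)


@dataclass
class Recording:
    """A labeled multichannel time series.

    Parameters
    ----------
    channel_labels : list of str
        One label per data row.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Sample values in microvolts.
    reference_note : str
        Free-text provenance of the reference scheme.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """A stack of equal-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, epoch_length).
    """

    band: BandDefinition | None
    fs: float
    epochs: np.ndarray
    epoch_length: int
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, sample)")
        if self.epochs.shape[0] < 1:
            raise ValueError("EpochSet needs at least one epoch")
        if self.epochs.shape[2] != self.epoch_length:
            raise ValueError(
                f"epoch_length {self.epoch_length} != trailing dim "
                f"{self.epochs.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def rereference(rec: Recording, ref_labels: list[str]) -> Recording:
    """Subtract the mean of the reference channels and drop them.

    Raises ``ValueError`` naming any reference label absent from the
    recording.
    """
    missing = [r for r in ref_labels if r not in rec.channel_labels]
    if missing:
        raise ValueError(f"reference label(s) not found: {', '.join(missing)}")
    ref_idx = [rec.channel_labels.index(r) for r in ref_labels]
    ref_mean = rec.data[ref_idx].mean(axis=0)
    keep = [i for i in range(rec.n_channels) if i not in ref_idx]
    data = rec.data[keep] - ref_mean
    labels = [rec.channel_labels[i] for i in keep]
    return Recording(
        labels, rec.fs, data,
        reference_note=f"re-referenced to mean of {','.join(ref_labels)}",
    )


def bandpass(rec: Recording, band: BandDefinition, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass filter.

    A 4th-order design rolls off at ~24 dB per octave beyond each corner;
    forward-backward application (``sosfiltfilt``) cancels the filter phase
    so downstream instantaneous-phase estimates are unbiased.
    """
    band.validate_against(rec.fs)
    sos = signal.butter(
        order, [band.low, band.high], btype="bandpass", fs=rec.fs, output="sos"
    )
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(
        list(rec.channel_labels), rec.fs, data,
        reference_note=rec.reference_note,
    )


def epoch(rec: Recording, epoch_seconds: float, band: BandDefinition | None = None) -> EpochSet:
    """Cut consecutive non-overlapping epochs from the start of a recording.

    The trailing partial epoch is discarded. Raises if the recording is
    shorter than one epoch.
    """
    if epoch_seconds <= 0:
        raise ValueError(f"epoch_seconds must be positive, got {epoch_seconds}")
    epoch_length = int(round(rec.fs * epoch_seconds))
    n_epochs = rec.n_samples // epoch_length
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one epoch "
            f"of {epoch_length}"
        )
    trimmed = rec.data[:, : n_epochs * epoch_length]
    stack = trimmed.reshape(rec.n_channels, n_epochs, epoch_length)
    stack = np.ascontiguousarray(np.swapaxes(stack, 0, 1))
    return EpochSet(band, rec.fs, stack, epoch_length, list(rec.channel_labels))


def reject_artifacts(
    es: EpochSet, ptp_threshold: float = 100.0, n_keep: int = 10
) -> EpochSet:
    """Keep the first ``n_keep`` epochs passing a peak-to-peak screen.

    An epoch is clean iff every channel's peak-to-peak amplitude is at most
    ``ptp_threshold`` (microvolts). Raises when no epoch is clean, listing
    per-epoch maxima in the message; logs a warning when fewer than
    ``n_keep`` clean epochs exist.
    """
    if n_keep < 1:
        raise ValueError(f"n_keep must be >= 1, got {n_keep}")
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # (epoch, channel)
    worst = ptp.max(axis=1)
    clean = np.flatnonzero(worst <= ptp_threshold)
    if clean.size == 0:
        maxima = ", ".join(f"epoch {i}: {w:.3g}" for i, w in enumerate(worst))
        raise ValueError(
            f"no epoch passes peak-to-peak threshold {ptp_threshold}; "
            f"per-epoch maxima: {maxima}"
        )
    if clean.size < n_keep:
        logger.warning(
            "only %d clean epochs available (requested %d)", clean.size, n_keep
        )
    kept = clean[:n_keep]
    return replace(es, epochs=es.epochs[kept])
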