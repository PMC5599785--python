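"""Phase lag index (PLI) connectivity from analytic-signal phases.

For two phase series the PLI is ``|mean over samples of
sign(sin(phi_a - phi_b))|`` with ``sign(0) = 0``: it quantifies how
consistently one signal leads or lags the other, ignoring zero-lag
(and anti-phase) relationships, which makes it insensitive to common
sources picked up instantaneously by several sensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PhaseEpoch",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
    "average_pli",
    "mean_pli",
]

_MIN_SAMPLES = 64


@dataclass
class PhaseEpoch:
    """Instantaneous phases, channels x samples, wrapped to (-pi, pi]."""

    phases: np.ndarray
    fs: float
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValueError("phases must be 2-D (channel, sample)")

    @property
    def n_channels(self) -> int:
        return self.phases.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise PLI weights with zero diagonal, entries in [0, 1]."""

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n}x{n} matrix")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def instantaneous_phase(
    epoch: np.ndarray,
    fs: float,
    labels: list[str] | None = None,
    trim: int = 0,
) -> PhaseEpoch:
    """Per-channel phase of the analytic signal (Hilbert transform).

    ``trim`` drops that many samples from each end after the transform,
    discarding Hilbert edge transients (default 0: epochs are long enough
    that end effects are negligible at band frequencies).

    Raises for constant channels (phase undefined) and for epochs shorter
    than 64 samples.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] < _MIN_SAMPLES:
        raise ValueError(
            f"need >= {_MIN_SAMPLES} samples for phase estimation, "
            f"got {epoch.shape[1]}"
        )
    variances = epoch.var(axis=1)
    flat = np.flatnonzero(variances == 0)
    if flat.size:
        raise ValueError(
            f"channel(s) {flat.tolist()} are constant; phase undefined"
        )
    if trim < 0 or 2 * trim >= epoch.shape[1]:
        raise ValueError(f"trim {trim} leaves no samples")
    analytic = hilbert(epoch, axis=1)
    phases = np.angle(analytic)
    # np.angle returns values in [-pi, pi]; fold the closed lower edge.
    phases[phases == -np.pi] = np.pi
    if trim:
        phases = phases[:, trim:-trim]
    return PhaseEpoch(phases, fs, labels)


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI between two phase series: |<sign(sin(phi_a - phi_b))>|.

    Symmetric in its arguments; sign(0) contributes 0.
    """
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError(
            f"length mismatch: {phase_a.shape} vs {phase_b.shape}"
        )
    return float(abs(np.mean(np.sign(np.sin(phase_a - phase_b)))))


def pli_matrix(pe: PhaseEpoch) -> ConnectivityMatrix:
    """All-pairs PLI for one epoch; symmetric with a zero diagonal."""
    n = pe.n_channels
    if n < 2:
        raise ValueError(f"need >= 2 channels, got {n}")
    # sin(a - b) == Im(e^{ia} * conj(e^{ib})); pairwise via one complex row
    # product per channel keeps memory at O(n * samples).
    z = np.exp(1j * pe.phases)
    weights = np.zeros((n, n))
    for i in range(n - 1):
        cross = z[i] * np.conj(z[i + 1 :])
        weights[i, i + 1 :] = np.abs(np.mean(np.sign(cross.imag), axis=1))
    weights = weights + weights.T
    labels = pe.channel_labels or [f"ch{i:02d}" for i in range(n)]
    return ConnectivityMatrix(list(labels), weights)


def average_pli(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of same-shape, same-label matrices."""
    if not mats:
        raise ValueError("need at least one matrix")
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("label mismatch across matrices")
    mean = np.mean([m.weights for m in mats], axis=0)
    return ConnectivityMatrix(list(labels), mean)


def mean_pli(m: ConnectivityMatrix) -> float:
    """Mean of the strictly-upper-triangle entries."""
    n = m.n_channels
    if n < 2:
        raise ValueError("need >= 2 channels")
    iu = np.triu_indices(n, k=1)
    return float(m.weights[iu].mean())
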