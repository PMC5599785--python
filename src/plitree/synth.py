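"""Surrogate multichannel EEG with known phase-coupling topology.

Each channel is ``amplitude * sin(theta_i(t))``. Channels without a driver
are free oscillators whose constant frequency is drawn inside the carrier
band; a coupled follower tracks its driver's phase plus a constant lag plus
phase jitter whose size shrinks with coupling strength. Optional zero-lag
channel mixing emulates instantaneous source spread (volume conduction /
common reference), and independent white sensor noise is added last.

The phase jitter has two components: a slow Ornstein-Uhlenbeck drift
(correlation time ``JITTER_TAU`` seconds) that survives band-pass
filtering, and a small white component. Both standard deviations scale
with ``1 - coupling_strength``, so strength 1 means exact phase tracking.
A purely white jitter would be almost entirely removed by the narrow-band
filter applied downstream, making every coupling look perfect regardless
of strength; the slow component keeps the strength parameter meaningful
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .preprocess import BandDefinition, Recording
from .stats import GROUP_NONSMOKER, GROUP_SMOKER, SubjectRecord

__all__ = [
    "TopologySpec",
    "star_spec",
    "chain_spec",
    "null_spec",
    "generate_recording",
    "generate_group_dataset",
]

#: OU correlation time (s) and scale factors for follower phase jitter.
JITTER_TAU = 0.3
JITTER_SLOW_SCALE = 2.0
JITTER_WHITE_SCALE = 0.3

#: Free-oscillator frequencies stay this fraction inside each band edge so
#: jitter sidebands remain mostly in band.
_BAND_MARGIN = 0.15

#: Default driver->follower phase lag (radians) used by the presets.
DEFAULT_LAG = 1.0


@dataclass(frozen=True)
class TopologySpec:
    """Ground-truth coupling layout for one surrogate recording.

    ``coupling_edges`` lists (driver, follower, phase_lag, strength)
    tuples; a follower may itself drive other channels (chains), but no
    channel may have two drivers. ``amplitude`` 0 with positive
    ``noise_sd`` yields pure-noise channels.
    """

    n_channels: int
    coupling_edges: tuple[tuple[int, int, float, float], ...] = ()
    carrier_band: BandDefinition = BandDefinition("alpha", 8.0, 13.0)
    noise_sd: float = 0.0
    mixing: np.ndarray | None = None
    seed: int = 0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        seen_followers: set[int] = set()
        for edge in self.coupling_edges:
            if len(edge) != 4:
                raise ValueError(
                    f"coupling edge must be (i, j, lag, strength), got {edge!r}"
                )
            i, j, lag, strength = edge
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(
                    f"edge ({i}, {j}) references a channel >= {self.n_channels}"
                )
            if i == j:
                raise ValueError(f"self-coupling on channel {i}")
            if not (-np.pi < lag <= np.pi):
                raise ValueError(f"phase lag {lag} outside (-pi, pi]")
            if not (0.0 <= strength <= 1.0):
                raise ValueError(f"coupling strength {strength} outside [0, 1]")
            if j in seen_followers:
                raise ValueError(f"channel {j} has more than one driver")
            seen_followers.add(j)
        if self.mixing is not None:
            mix = np.asarray(self.mixing, dtype=float)
            if mix.shape != (self.n_channels, self.n_channels):
                raise ValueError(
                    f"mixing matrix must be {self.n_channels} x "
                    f"{self.n_channels}, got {mix.shape}"
                )
            if not np.all(np.isfinite(mix)):
                raise ValueError("mixing matrix contains non-finite entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def star_spec(
    n_channels: int,
    band: BandDefinition,
    strength: float,
    lag: float = DEFAULT_LAG,
    seed: int = 0,
    **kwargs,
) -> TopologySpec:
    """Hub topology: channel 0 drives every other channel at a common lag.

    Follower pairs then share a (noisy) zero-lag relation the PLI
    discounts, so only hub edges survive into the recovered tree.
    """
    edges = tuple((0, j, lag, strength) for j in range(1, n_channels))
    return TopologySpec(n_channels, edges, band, seed=seed, **kwargs)


def chain_spec(
    n_channels: int,
    band: BandDefinition,
    strength: float,
    lag: float = DEFAULT_LAG,
    seed: int = 0,
    **kwargs,
) -> TopologySpec:
    """Sequential topology: channel k drives channel k+1, lag per hop."""
    edges = tuple((j, j + 1, lag, strength) for j in range(n_channels - 1))
    return TopologySpec(n_channels, edges, band, seed=seed, **kwargs)


def null_spec(
    n_channels: int,
    band: BandDefinition,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TopologySpec:
    """Pure-noise channels: no oscillators, no coupling."""
    return TopologySpec(
        n_channels, (), band, noise_sd=noise_sd, seed=seed, amplitude=0.0
    )


def _follower_order(
    spec: TopologySpec,
) -> list[tuple[int, int, float, float]]:
    """Coupling edges sorted so every driver is generated before its follower."""
    pending = list(spec.coupling_edges)
    resolved = {
        c
        for c in range(spec.n_channels)
        if c not in {e[1] for e in spec.coupling_edges}
    }
    ordered: list[tuple[int, int, float, float]] = []
    while pending:
        progress = False
        for edge in list(pending):
            if edge[0] in resolved:
                ordered.append(edge)
                resolved.add(edge[1])
                pending.remove(edge)
                progress = True
        if not progress:
            cyc = sorted({e[1] for e in pending})
            raise ValueError(f"coupling graph contains a cycle through {cyc}")
    return ordered


def _ou_series(
    rng: np.random.Generator, n: int, sd: float, tau: float, fs: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path with sd ``sd``."""
    if sd == 0:
        return np.zeros(n)
    alpha = np.exp(-1.0 / (tau * fs))
    innov = rng.normal(0.0, sd * np.sqrt(1 - alpha**2), n)
    innov[0] = rng.normal(0.0, sd)
    # AR(1) recursion out[k] = alpha * out[k-1] + innov[k]
    return lfilter([1.0], [1.0, -alpha], innov)


def generate_recording(
    spec: TopologySpec, fs: float, duration: float
) -> Recording:
    """Simulate one multichannel recording from a topology spec.

    Requires ``fs`` above twice the carrier band's upper edge and at least
    16 s of data (two default-length epochs). Identical specs (including
    seed) produce bit-identical recordings.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 2 * spec.carrier_band.high:
        raise ValueError(
            f"fs {fs} must exceed twice the carrier band upper edge "
            f"({spec.carrier_band.high} Hz)"
        )
    if duration < 16.0:
        raise ValueError(
            f"duration {duration} s too short: need >= 16 s (two 8-s epochs)"
        )
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_samples) / fs
    band = spec.carrier_band
    margin = _BAND_MARGIN * (band.high - band.low)

    theta = np.zeros((spec.n_channels, n_samples))
    followers = {e[1] for e in spec.coupling_edges}
    for c in range(spec.n_channels):
        if c in followers:
            continue
        freq = rng.uniform(band.low + margin, band.high - margin)
        phase0 = rng.uniform(-np.pi, np.pi)
        theta[c] = 2 * np.pi * freq * t + phase0
    for i, j, lag, strength in _follower_order(spec):
        slow_sd = (1.0 - strength) * JITTER_SLOW_SCALE
        white_sd = (1.0 - strength) * JITTER_WHITE_SCALE
        jitter = _ou_series(rng, n_samples, slow_sd, JITTER_TAU, fs)
        if white_sd > 0:
            jitter = jitter + rng.normal(0.0, white_sd, n_samples)
        theta[j] = theta[i] + lag + jitter

    data = spec.amplitude * np.sin(theta)
    if spec.mixing is not None:
        mix = np.asarray(spec.mixing, dtype=float)
        if not np.array_equal(mix, np.eye(spec.n_channels)):
            data = mix @ data
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, data.shape)

    labels = [f"ch{c:02d}" for c in range(spec.n_channels)]
    return Recording(
        labels, fs, data,
        reference_note=f"synthetic (seed={spec.seed})",
    )


def _synthetic_covariates(rng: np.random.Generator) -> dict[str, float]:
    """Plausible smoking-behavior covariates for one surrogate smoker."""
    cpd = float(rng.integers(5, 26))
    onset = float(rng.integers(14, 23))
    years = float(rng.uniform(1.0, 8.0))
    return {
        "ftnd": float(rng.integers(1, 10)),
        "cigarettes_per_day": cpd,
        "pack_years": round(cpd / 20.0 * years, 3),
        "onset_age": onset,
    }


def generate_group_dataset(
    n_per_group: int,
    spec_a: TopologySpec,
    spec_b: TopologySpec,
    fs: float,
    duration: float,
    seed: int,
) -> list[tuple[Recording, SubjectRecord]]:
    """Two cohorts of surrogate subjects with per-subject derived seeds.

    Group A (``spec_a``) subjects are labeled smokers and receive synthetic
    behavioral covariates; group B subjects are nonsmokers without
    covariates. Requires ``n_per_group >= 2`` so group statistics are
    defined downstream.
    """
    if n_per_group < 2:
        raise ValueError(
            f"n_per_group must be >= 2 (group statistics undefined), "
            f"got {n_per_group}"
        )
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**63 - 1, size=2 * n_per_group)
    out: list[tuple[Recording, SubjectRecord]] = []
    for k in range(n_per_group):
        spec = replace(spec_a, seed=int(subject_seeds[k]))
        rec = generate_recording(spec, fs, duration)
        covariates = _synthetic_covariates(master)
        out.append(
            (
                rec,
                SubjectRecord(
                    subject_id=f"smoker{k + 1:02d}",
                    group=GROUP_SMOKER,
                    covariates=covariates,
                ),
            )
        )
    for k in range(n_per_group):
        spec = replace(spec_b, seed=int(subject_seeds[n_per_group + k]))
        rec = generate_recording(spec, fs, duration)
        out.append(
            (
                rec,
                SubjectRecord(
                    subject_id=f"nonsmoker{k + 1:02d}",
                    group=GROUP_NONSMOKER,
                ),
            )
        )
    return out
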