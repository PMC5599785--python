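from __future__ import annotations

import numpy as np
import pytest

from plitree.connectivity import ConnectivityMatrix
from plitree.mst import SpanningTree
from plitree.preprocess import BandDefinition, Recording

ALPHA = BandDefinition("alpha", 8.0, 13.0)


def star_tree(n: int) -> SpanningTree:
    edges = [(0, j, 1.0) for j in range(1, n)]
    return SpanningTree(n, edges, [f"ch{i:02d}" for i in range(n)])


def path_tree(n: int) -> SpanningTree:
    edges = [(j, j + 1, 1.0) for j in range(n - 1)]
    return SpanningTree(n, edges, [f"ch{i:02d}" for i in range(n)])


def random_connectivity(rng: np.random.Generator, n: int) -> ConnectivityMatrix:
    w = rng.uniform(0.0, 1.0, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix([f"ch{i:02d}" for i in range(n)], w)


def prufer_tree(rng: np.random.Generator, n: int) -> SpanningTree:
    """Uniform random labeled tree via a random Prufer sequence."""
    seq = rng.integers(0, n, size=n - 2).tolist()
    return decode_prufer(seq, n)


def decode_prufer(seq: list[int], n: int) -> SpanningTree:
    degree = [1] * n
    for s in seq:
        degree[s] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, s), max(leaf, s), 1.0))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    a, b = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((min(a, b), max(a, b), 1.0))
    return SpanningTree(n, edges, [f"ch{i:02d}" for i in range(n)])


def max_tree_weight_bruteforce(m: ConnectivityMatrix) -> float:
    """Exhaustive max spanning-tree weight over all n^(n-2) Prufer trees."""
    import itertools

    n = m.n_channels
    if n == 2:
        return float(m.weights[0, 1])
    best = -np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        t = decode_prufer(list(seq), n)
        w = sum(m.weights[i, j] for i, j, _ in t.edges)
        best = max(best, w)
    return float(best)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def alpha_band() -> BandDefinition:
    return ALPHA


@pytest.fixture
def sine_recording() -> Recording:
    """Four-channel 10 Hz recording with known constant phase lags."""
    fs = 512.0
    t = np.arange(int(fs * 16)) / fs
    base = 2 * np.pi * 10.0 * t
    data = np.vstack(
        [
            np.sin(base),
            np.sin(base - np.pi / 4),
            np.sin(base - np.pi / 2),
            np.cos(base),
        ]
    )
    return Recording(["a", "b", "c", "d"], fs, data)
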