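"""Shared fixtures: small synthetic configs and independent graph oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from bindnet import SimulationConfig

# The PSD repair of strongly planted targets is by design and logged via a
# warning; tests that plant large effects silence it explicitly.
PSD_WARNING = "target correlation repaired to PSD"


@pytest.fixture
def small_config() -> SimulationConfig:
    """A 6-subject, 10-region design small enough for fast unit tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SimulationConfig(
            n_subjects=6,
            n_regions=10,
            n_frames=120,
            planted_edges=((0, 1), (0, 2), (1, 2)),
            delta_r=0.3,
            phi=np.full(10, 0.3),
            seed=11,
        )


def brute_force_local_efficiency(mask: np.ndarray, v: int) -> float:
    """Independent oracle: all-pairs BFS over the neighbor-induced subgraph."""
    mask = np.asarray(mask, dtype=bool)
    neighbors = [u for u in range(mask.shape[0]) if mask[v, u]]
    k = len(neighbors)
    if k < 2:
        return 0.0
    total = 0.0
    for i in neighbors:
        # BFS from i, restricted to the neighbor set
        dist = {i: 0}
        frontier = [i]
        while frontier:
            nxt = []
            for a in frontier:
                for b in neighbors:
                    if mask[a, b] and b not in dist:
                        dist[b] = dist[a] + 1
                        nxt.append(b)
            frontier = nxt
        for j in neighbors:
            if j != i and j in dist:
                total += 1.0 / dist[j]
    return total / (k * (k - 1))


def random_connected_mask(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    """Random symmetric mask guaranteed connected via a random spanning tree."""
    mask = rng.random((n, n)) < p
    mask = np.triu(mask, 1)
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        i, j = min(a, b), max(a, b)
        mask[i, j] = True
    mask = mask | mask.T
    np.fill_diagonal(mask, False)
    return mask
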