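"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import rootph as rp


# ---------------------------------------------------------------------------
# oracles


def brute_force_edges(coords: np.ndarray) -> int:
    """All-pairs count of voxel pairs at Chebyshev distance exactly 1."""
    n = len(coords)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(coords[i] - coords[j])) == 1:
                count += 1
    return count


def superlevel_component_count(net, values: np.ndarray, t: float) -> int:
    """Connected components of the subgraph {f >= t} by direct construction."""
    keep = values >= t
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return 0
    remap = -np.ones(net.n_vertices, dtype=int)
    remap[idx] = np.arange(idx.size)
    if net.n_edges:
        emask = keep[net.edges[:, 0]] & keep[net.edges[:, 1]]
        e = remap[net.edges[emask]]
    else:
        e = np.empty((0, 2), dtype=int)
    adj = csr_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                     shape=(idx.size, idx.size))
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


def alive_bar_count(bars: np.ndarray, t: float) -> int:
    """Bars alive at level t: birth >= t > death, plus the essential bar at t <= 0."""
    alive = int(np.sum((bars[:, 0] >= t) & (bars[:, 1] < t)))
    if t <= 0:
        alive += 1
    return alive


def brute_force_bottleneck(p1: np.ndarray, p2: np.ndarray) -> float:
    """Exhaustive minimax over all partial matchings (small diagrams only)."""
    p1 = np.asarray(p1, float).reshape(-1, 2)
    p2 = np.asarray(p2, float).reshape(-1, 2)
    d1 = np.abs(p1[:, 0] - p1[:, 1]) / 2
    d2 = np.abs(p2[:, 0] - p2[:, 1]) / 2
    n1, n2 = len(p1), len(p2)
    best = np.inf
    idx2 = range(n2)
    for k in range(0, min(n1, n2) + 1):
        for sub1 in itertools.combinations(range(n1), k):
            rest1 = [i for i in range(n1) if i not in sub1]
            for sub2 in itertools.permutations(idx2, k):
                cost = 0.0
                for i, j in zip(sub1, sub2):
                    cost = max(cost, np.max(np.abs(p1[i] - p2[j])))
                for i in rest1:
                    cost = max(cost, d1[i])
                for j in set(idx2) - set(sub2):
                    cost = max(cost, d2[j])
                best = min(best, cost)
    return float(best)


def random_diagram(rng: np.random.Generator, max_points: int = 6) -> np.ndarray:
    """Random diagram with birth >= death >= 0, up to max_points points."""
    n = int(rng.integers(0, max_points + 1))
    death = rng.uniform(0, 10, n)
    birth = death + rng.uniform(0, 10, n)
    return np.column_stack([birth, death])


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def straight_root():
    """An 11-voxel vertical root (z = 0..10)."""
    vs = rp.VoxelSet(np.array([[0, 0, z] for z in range(11)]))
    return rp.build_network(vs)


@pytest.fixture
def y_tree():
    """Vertical axis z = 0..10 with a diagonal 3-voxel lateral leaving at z = 5."""
    coords = [[0, 0, z] for z in range(11)] + [[k, 0, 5 + k] for k in range(1, 4)]
    vs = rp.VoxelSet(np.array(coords))
    return rp.build_network(vs)


@pytest.fixture(scope="session")
def small_population():
    """20 synthetic roots with default spec, shared across tests."""
    return rp.make_population(20, seed=11)


def varied_spec_sampler(k, rng):
    """Population sampler spanning sparse to dense architectures."""
    return rp.SyntheticRootSpec(
        primary_length=int(rng.integers(50, 90)),
        lateral_count_mean=float(rng.uniform(2, 8)),
        lateral_length_mean=float(rng.uniform(12, 28)),
        lateral_length_sd=4.0,
        soil_angle_mean=float(rng.uniform(10, 75)),
        soil_angle_sd=10.0,
        tortuosity=float(rng.uniform(0.0, 0.15)),
    )
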