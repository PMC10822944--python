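"""Bottleneck distance between persistence diagrams and population distance matrices.

The bottleneck distance is the min over partial matchings of the maximum L-inf
displacement, where unmatched points pair to the diagonal at cost |birth -
death| / 2.  Because every candidate optimal cost is either a point-to-point
L-inf distance or a diagonal cost, the optimum is found exactly by a binary
search over that finite candidate set, testing feasibility of each threshold
with a maximum bipartite matching (augmenting paths).

Two barcodes per root (geodesic and depth) combine into a single dissimilarity
sqrt(d_geo^2 + d_depth^2), which is itself a metric; the population-level
matrix of these values feeds multidimensional scaling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .filtration import PersistenceBarcode, PersistenceDiagram, barcode_to_diagram

__all__ = [
    "DistanceMatrix",
    "bottleneck_distance",
    "combined_distance",
    "pairwise_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with sample identifiers."""

    values: np.ndarray
    sample_ids: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.sample_ids) != vals.shape[0]:
            raise ValueError("sample_ids length must match matrix size")
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(vals < 0) or np.any(np.diag(vals) != 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.sample_ids))


def _diag_costs(pts: np.ndarray) -> np.ndarray:
    return np.abs(pts[:, 0] - pts[:, 1]) / 2.0


def _feasible(cost: np.ndarray, diag1: np.ndarray, diag2: np.ndarray, c: float) -> bool:
    """Can every diagram point be matched within threshold c?

    Standard reduction: augment each diagram with one virtual diagonal slot per
    point of the other diagram.  Point i of diagram 1 may match point j of
    diagram 2 (cost[i, j] <= c) or its own diagonal slot (diag1[i] <= c);
    diagonal slots match each other at zero cost.  A perfect matching of the
    (n1 + n2) x (n2 + n1) bipartite graph exists iff cost c is achievable.
    """
    n1, n2 = len(diag1), len(diag2)
    size = n1 + n2
    rows, cols = [], []
    if n1 and n2:
        ii, jj = np.nonzero(cost <= c)
        rows.extend(ii)
        cols.extend(jj)
    ok1 = np.flatnonzero(diag1 <= c)  # diagram-1 point i -> its diagonal slot
    rows.extend(ok1)
    cols.extend(n2 + ok1)
    ok2 = np.flatnonzero(diag2 <= c)  # diagram-2 point j <- its diagonal slot
    rows.extend(n1 + ok2)
    cols.extend(ok2)
    # diagonal slots pair freely with each other
    di, dj = np.meshgrid(np.arange(n1, size), np.arange(n2, size), indexing="ij")
    rows.extend(di.ravel())
    cols.extend(dj.ravel())
    graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                       shape=(size, size))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return bool(np.all(match >= 0))


def bottleneck_distance(d1, d2) -> float:
    """Exact bottleneck distance between two persistence diagrams.

    Accepts diagrams or barcodes; empty diagrams are allowed (all points of the
    other diagram then pair to the diagonal).  The candidate-cost set — all
    point-to-point L-inf distances plus all diagonal costs — is binary-searched
    for the smallest feasible threshold, so the result is exact.
    """
    p1 = _as_points(d1)
    p2 = _as_points(d2)
    n1, n2 = len(p1), len(p2)
    if n1 == 0 and n2 == 0:
        return 0.0
    diag1 = _diag_costs(p1)
    diag2 = _diag_costs(p2)
    if n1 and n2:
        cost = np.max(np.abs(p1[:, None, :] - p2[None, :, :]), axis=2)
        candidates = np.concatenate([cost.ravel(), diag1, diag2])
    else:
        cost = np.empty((n1, n2))
        candidates = np.concatenate([diag1, diag2])
    candidates = np.unique(candidates)
    lo, hi = 0, len(candidates) - 1
    if _feasible(cost, diag1, diag2, candidates[lo]):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _feasible(cost, diag1, diag2, candidates[mid]):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])


def _as_points(d) -> np.ndarray:
    if isinstance(d, PersistenceBarcode):
        d = barcode_to_diagram(d)
    if isinstance(d, PersistenceDiagram):
        return d.points
    return np.asarray(d, dtype=float).reshape(-1, 2)


def combined_distance(geo_d: float, depth_d: float) -> float:
    """sqrt(geo^2 + depth^2): the combined geodesic+depth dissimilarity."""
    if geo_d < 0 or depth_d < 0:
        raise ValueError("distances must be non-negative")
    return float(np.hypot(geo_d, depth_d))


def pairwise_matrix(samples, mode: str = "geodesic+depth",
                    sample_ids=None) -> DistanceMatrix:
    """Population distance matrix from per-sample (geo, depth) diagram pairs.

    ``samples`` is a sequence of (geo_diagram, depth_diagram) pairs (barcodes
    accepted).  Mode ``"geodesic"`` uses only the geodesic diagrams; mode
    ``"geodesic+depth"`` combines the two bottleneck distances per entry.
    """
    if mode not in ("geodesic", "geodesic+depth"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if sample_ids is None:
        sample_ids = [f"s{k:03d}" for k in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            g = bottleneck_distance(samples[i][0], samples[j][0])
            if mode == "geodesic":
                out[i, j] = out[j, i] = g
            else:
                h = bottleneck_distance(samples[i][1], samples[j][1])
                out[i, j] = out[j, i] = combined_distance(g, h)
    return DistanceMatrix(out, tuple(sample_ids))
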