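"""Superlevel-set H0 persistence of scalar functions on a root network.

Two functions drive the analysis.  The *geodesic* function assigns each voxel
its along-network shortest-path distance to the top of the root (the gel
surface), so bar lengths read as branch lengths.  The *depth* function assigns
the straight vertical distance to the top plane, so shallow (near-horizontal)
branches produce short bars — this is what lets the combined analysis see root
angle.

The filtration sweeps a threshold t downward from the function maximum and
tracks connected components of the superlevel subgraph {f >= t} (an edge enters
when its lower endpoint does, since its value is the min of its endpoints).  A
component is born at the exact function value of its maximal vertex — the
integer step size only schedules the sweep, so barcodes are step-independent
for any step no larger than the smallest positive value gap.  When two
components merge, the one with the smaller birth dies (the elder rule: at the
moment of merging, the shorter bar dies); the survivor's death is recorded as
0 once the sweep reaches the function minimum, so every bar is a finite point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .voxels import RootNetwork, component_labels

__all__ = [
    "VertexFunction",
    "EdgeFunction",
    "PersistenceBarcode",
    "PersistenceDiagram",
    "geodesic_function",
    "depth_function",
    "edge_values",
    "h0_barcode",
    "barcode_to_diagram",
]


class DisconnectedNetworkError(ValueError):
    """Raised when an operation requires a connected network; use largest_component."""


@dataclass(frozen=True)
class VertexFunction:
    """Per-vertex scalar field on a RootNetwork, in physical length units."""

    name: str  # "geodesic" or "depth"
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.all(np.isfinite(vals)):
            raise ValueError("vertex function has non-finite values")


@dataclass(frozen=True)
class EdgeFunction:
    """Per-edge scalar: the minimum of the two endpoint values."""

    values: np.ndarray


@dataclass(frozen=True)
class PersistenceBarcode:
    """Multiset of (birth, death) bars, birth >= death >= 0.

    Exactly one bar (the essential one) has death 0 on a connected network.
    Bars are stored sorted by descending birth, then descending death.
    """

    bars: np.ndarray  # (k, 2) float
    function: str = ""
    step: float = 1.0

    def __post_init__(self):
        bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        if bars.shape[0] == 0:
            raise ValueError("barcode must contain at least one bar")
        if np.any(bars[:, 0] < bars[:, 1]) or np.any(bars[:, 1] < 0):
            raise ValueError("bars must satisfy birth >= death >= 0")
        order = np.lexsort((-bars[:, 1], -bars[:, 0]))
        object.__setattr__(self, "bars", bars[order])

    def __len__(self) -> int:
        return self.bars.shape[0]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Equivalent 2D-scatter view of a barcode: points (birth, death)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def _require_connected(net: RootNetwork) -> None:
    n_comp, _ = component_labels(net)
    if n_comp != 1:
        raise DisconnectedNetworkError(
            f"network has {n_comp} components; apply largest_component first"
        )


def top_vertices(net: RootNetwork) -> np.ndarray:
    """Indices of vertices in the minimal-depth slice (the top plane)."""
    depth = net.coords[:, net.depth_axis]
    return np.flatnonzero(depth == depth.min())


def geodesic_function(net: RootNetwork, top="auto") -> VertexFunction:
    """Shortest along-network distance from each vertex to the top of the root.

    Edge weights are Euclidean edge lengths, so the value approximates the true
    curved length of root between a voxel and the gel surface.  ``top`` is a
    vertex index array, or ``"auto"`` for all vertices in the minimal-depth
    slice.  The value is 0 exactly on the top set.
    """
    if isinstance(top, str) and top == "auto":
        top_idx = top_vertices(net)
    else:
        top_idx = np.asarray(top, dtype=np.int64)
    if top_idx.size == 0:
        raise ValueError("top vertex set is empty")
    dist = dijkstra(net.adjacency(), directed=False, indices=top_idx, min_only=True)
    if not np.all(np.isfinite(dist)):
        raise DisconnectedNetworkError(
            "some vertices are unreachable from the top set; "
            "apply largest_component first"
        )
    return VertexFunction("geodesic", dist)


def depth_function(net: RootNetwork) -> VertexFunction:
    """Straight vertical distance from each vertex to the top plane."""
    depth = net.coords[:, net.depth_axis].astype(float)
    return VertexFunction("depth", (depth - depth.min()) * net.spacing)


def edge_values(net: RootNetwork, f: VertexFunction) -> EdgeFunction:
    """Per-edge value: min of the endpoint values (edge enters with its lower end)."""
    if f.values.shape[0] != net.n_vertices:
        raise ValueError("function not defined on all vertices")
    if net.n_edges == 0:
        return EdgeFunction(np.empty(0))
    return EdgeFunction(np.minimum(f.values[net.edges[:, 0]], f.values[net.edges[:, 1]]))


def h0_barcode(net: RootNetwork, f: VertexFunction, step: float = 1.0) -> PersistenceBarcode:
    """H0 persistence barcode of the decreasing-threshold (superlevel) sweep.

    Vertices enter in order of decreasing function value; a vertex with no
    previously-entered neighbour births a component at its exact function
    value.  When an entering vertex connects two components, the younger one
    (smaller birth; ties: the one whose maximal vertex has the larger index)
    dies at the entering vertex's value.  The surviving essential component is
    assigned death 0.

    ``step`` is the sweep granularity of the level-set narrative; births and
    deaths are recorded at exact function values, so the result is independent
    of ``step`` whenever it is at most the smallest positive value gap.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    vals = f.values
    if np.any(vals < 0):
        raise ValueError("function values must be non-negative")
    _require_connected(net)
    n = net.n_vertices

    # descending value; ties by ascending index so earlier vertices enter first
    order = np.lexsort((np.arange(n), -vals))
    neighbors = net.neighbor_lists()

    parent = np.arange(n)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    entered = np.zeros(n, dtype=bool)
    birth_val = np.empty(n)    # per component root: birth value
    birth_vtx = np.empty(n, dtype=np.int64)  # vertex attaining the birth
    bars: list[tuple[float, float]] = []

    for v in order:
        entered[v] = True
        birth_val[v] = vals[v]
        birth_vtx[v] = v
        for u in neighbors[v]:
            if not entered[u]:
                continue
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            # elder rule: larger birth survives; ties -> survivor is the
            # component whose representative (birth) vertex has smaller index
            key_u = (birth_val[ru], -birth_vtx[ru])
            key_v = (birth_val[rv], -birth_vtx[rv])
            survivor, loser = (ru, rv) if key_u >= key_v else (rv, ru)
            # zero-persistence pairs (a vertex absorbed at its own level) are
            # never visible at any threshold and are not recorded
            if birth_val[loser] > vals[v]:
                bars.append((birth_val[loser], vals[v]))
            parent[loser] = survivor

    # the one surviving component never dies within the sweep; cap at 0
    root = find(order[-1])
    bars.append((birth_val[root], 0.0))
    return PersistenceBarcode(np.asarray(bars), function=f.name, step=step)


def barcode_to_diagram(bc: PersistenceBarcode) -> PersistenceDiagram:
    """One diagram point (birth, death) per bar, multiplicity preserved."""
    return PersistenceDiagram(bc.bars.copy())
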