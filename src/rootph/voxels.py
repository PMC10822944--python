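"""Voxel representations of a root system and the connectivity graph built on them.

A scanned root arrives as a cloud of occupied lattice points (surface voxels
exported as PLY, a plain x,y,z table, or a dense binary tensor).  All input
routes converge on :class:`VoxelSet`; :func:`build_network` then connects every
pair of voxels that touch within a 3x3x3 neighbourhood (26-connectivity), with
edge lengths equal to the Euclidean distance between voxel centres.  That graph
is the object persistence is computed on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "VoxelSet",
    "RootNetwork",
    "read_voxel_ply",
    "write_voxel_ply",
    "read_voxel_coords",
    "read_voxel_tensor",
    "build_network",
    "largest_component",
    "cycle_rank",
]


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


class EmptyInputError(ValueError):
    """Raised when a voxel source contains no points."""


@dataclass(frozen=True)
class VoxelSet:
    """Occupied integer lattice points of one root system.

    Parameters
    ----------
    coords : ndarray of shape (n, 3), integer
        Unique lattice coordinates (x, y, z).
    spacing : float
        Physical length of one voxel edge; all distances scale with it.
    depth_axis : int
        Axis pointing down into the gel (default 2 = z, increasing downward).
        The "top plane" is the minimal coordinate along this axis.
    """

    coords: np.ndarray
    spacing: float = 1.0
    depth_axis: int = 2

    def __post_init__(self):
        coords = np.asarray(self.coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if coords.shape[0] == 0:
            raise EmptyInputError("voxel set is empty")
        if not np.issubdtype(coords.dtype, np.integer):
            raise ValueError("coords must be integers; quantize first")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        # canonical order: lexicographic by (x, y, z); also enforces uniqueness
        uniq = np.unique(coords, axis=0)
        if uniq.shape[0] != coords.shape[0]:
            raise ValueError("coords contain duplicates")
        object.__setattr__(self, "coords", uniq)

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class RootNetwork:
    """Graph over voxels: vertices are voxel centres, edges join 26-neighbours.

    ``edges`` is an (m, 2) array of vertex indices with i < j; ``lengths`` holds
    the Euclidean edge length (1, sqrt(2) or sqrt(3) times the spacing).
    """

    coords: np.ndarray
    edges: np.ndarray
    lengths: np.ndarray
    spacing: float = 1.0
    depth_axis: int = 2
    _adj: csr_matrix = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> csr_matrix:
        """Sparse symmetric adjacency matrix weighted by edge length."""
        if self._adj is not None:
            return self._adj
        n = self.n_vertices
        if self.n_edges:
            i, j = self.edges[:, 0], self.edges[:, 1]
            adj = csr_matrix(
                (np.concatenate([self.lengths, self.lengths]),
                 (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(n, n),
            )
        else:
            adj = csr_matrix((n, n))
        object.__setattr__(self, "_adj", adj)
        return adj

    def neighbor_lists(self) -> list[np.ndarray]:
        adj = self.adjacency()
        return [adj.indices[adj.indptr[k]:adj.indptr[k + 1]] for k in range(self.n_vertices)]


def _quantize(points: np.ndarray, spacing: float) -> np.ndarray:
    """Snap physical coordinates onto the integer lattice (round half to even)."""
    # np.rint rounds ties to even, matching the documented convention
    return np.rint(np.asarray(points, dtype=float) / spacing).astype(np.int64)


def read_voxel_ply(path, spacing: float = 1.0, depth_axis: int = 2) -> VoxelSet:
    """Read a vertex-only PLY file (ASCII or binary little-endian) into a VoxelSet.

    Coordinates are divided by ``spacing`` and rounded to the nearest lattice
    point; duplicates collapse.  Raises :class:`FormatError` if the file has no
    vertex element and :class:`EmptyInputError` if the vertex list is empty.
    """
    import trimesh

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    try:
        obj = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on malformed headers
        raise FormatError(f"cannot parse PLY file {path!s}: {exc}") from exc
    verts = np.asarray(getattr(obj, "vertices", np.empty((0, 3))))
    if verts.ndim != 2 or verts.shape[1] != 3:
        raise FormatError(f"PLY file {path!s} has no x,y,z vertex element")
    if verts.shape[0] == 0:
        raise EmptyInputError(f"PLY file {path!s} contains no vertices")
    lattice = np.unique(_quantize(verts, spacing), axis=0)
    return VoxelSet(lattice, spacing=spacing, depth_axis=depth_axis)


def write_voxel_ply(vs: VoxelSet, path) -> None:
    """Write a VoxelSet as an ASCII vertex-only PLY (physical coordinates)."""
    phys = vs.coords.astype(float) * vs.spacing
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vs)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in phys:
            fh.write(f"{x:g} {y:g} {z:g}\n")


def read_voxel_coords(path, spacing: float = 1.0, depth_axis: int = 2) -> VoxelSet:
    """Read a CSV with integer columns x,y,z (header required) into a VoxelSet."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"coordinate CSV missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"coordinate CSV {path!s} has no rows")
    vals = df[["x", "y", "z"]].to_numpy()
    as_int = np.asarray(vals, dtype=float)
    if not np.all(as_int == np.floor(as_int)):
        raise FormatError("coordinate CSV contains non-integer values")
    lattice = np.unique(as_int.astype(np.int64), axis=0)
    return VoxelSet(lattice, spacing=spacing, depth_axis=depth_axis)


def read_voxel_tensor(tensor, spacing: float = 1.0, depth_axis: int = 2) -> VoxelSet:
    """Convert a dense binary 3D array (nonzero = occupied) into a VoxelSet."""
    arr = np.asarray(tensor)
    if arr.ndim != 3:
        raise FormatError("tensor must be 3-dimensional")
    coords = np.argwhere(arr != 0)
    if coords.shape[0] == 0:
        raise EmptyInputError("tensor contains no occupied voxels")
    return VoxelSet(coords.astype(np.int64), spacing=spacing, depth_axis=depth_axis)


# the 13 offsets covering each unordered neighbour pair exactly once
_HALF_OFFSETS = np.array(
    [off for idx in np.ndindex(3, 3, 3)
     if (off := tuple(x - 1 for x in idx)) > (0, 0, 0)],
    dtype=np.int64,
)


def build_network(vs: VoxelSet) -> RootNetwork:
    """Connect every voxel pair at Chebyshev distance 1 (26-connectivity).

    Edge lengths are Euclidean distances between voxel centres, i.e. 1, sqrt(2)
    or sqrt(3) times the spacing.
    """
    coords = vs.coords
    index = {tuple(c): k for k, c in enumerate(coords)}
    src, dst, lens = [], [], []
    for off in _HALF_OFFSETS:
        shifted = coords + off
        length = float(np.linalg.norm(off)) * vs.spacing
        for k, c in enumerate(shifted):
            j = index.get(tuple(c))
            if j is not None:
                src.append(k)
                dst.append(j)
                lens.append(length)
    if src:
        edges = np.column_stack([np.minimum(src, dst), np.maximum(src, dst)])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
        lengths = np.asarray(lens)[order]
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        lengths = np.empty(0)
    return RootNetwork(coords, edges, lengths, spacing=vs.spacing, depth_axis=vs.depth_axis)


def component_labels(net: RootNetwork) -> tuple[int, np.ndarray]:
    """Number of connected components and per-vertex component label."""
    return connected_components(net.adjacency(), directed=False)


def largest_component(net: RootNetwork) -> RootNetwork:
    """Restrict to the largest connected component.

    Ties are broken toward the component containing the lexicographically
    smallest voxel (vertex index 0 in canonical order).  Warns when the input
    was not connected.
    """
    if net.n_vertices == 0:
        raise EmptyInputError("network is empty")
    n_comp, labels = component_labels(net)
    if n_comp == 1:
        return net
    warnings.warn(
        f"network has {n_comp} connected components; keeping the largest",
        stacklevel=2,
    )
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(
        range(n_comp),
        key=lambda c: (sizes[c], -int(np.min(np.flatnonzero(labels == c)))),
    )
    keep = np.flatnonzero(labels == best)
    remap = -np.ones(net.n_vertices, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    if net.n_edges:
        mask = np.isin(net.edges[:, 0], keep) & np.isin(net.edges[:, 1], keep)
        edges = remap[net.edges[mask]]
        lengths = net.lengths[mask]
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        lengths = np.empty(0)
    return RootNetwork(net.coords[keep], edges, lengths,
                       spacing=net.spacing, depth_axis=net.depth_axis)


def cycle_rank(net: RootNetwork) -> int:
    """First Betti number |E| - |V| + #components; 0 means tree-structured.

    The gel-imaging workflow removes branch touches and loops by hand; this
    diagnostic flags voxel sets where that assumption fails.
    """
    if net.n_vertices == 0:
        return 0
    n_comp, _ = component_labels(net)
    return int(net.n_edges - net.n_vertices + n_comp)
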