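"""Synthetic voxelized root systems with known ground truth.

A stochastic geometric stand-in for gel-imaged root systems: one primary axis
growing downward from the top plane, plus lateral branches with controlled
counts, lengths, insertion depths and soil angles (measured from the
horizontal plane, so 0 deg is a horizontal lateral and 90 deg points straight
down).  Branches are rasterized as 26-connected digital lines whose dominant
axis advances every step, which guarantees each branch is a simple arc (no
incidental loops under 26-connectivity).

Attaching a branch to a straight voxel column cannot avoid creating small
cycles: any voxel touching a column voxel also touches one of its column
neighbours.  The generator therefore bends the primary axis sideways by one
voxel at each insertion point; the resulting corner is the one local
configuration where a branch voxel can touch the root at exactly one voxel.
Laterals whose remaining voxels would come within one voxel of the existing
root are resampled, so every generated root is a single connected component
with cycle rank 0 — the tree topology the imaging workflow enforces by manual
cleaning.

This is not a biological growth model; it only needs to span the trait space
the pipeline measures (tip counts, branch lengths, insertion depths, angles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .voxels import VoxelSet

__all__ = [
    "SyntheticRootSpec",
    "GroundTruth",
    "generate_root",
    "make_population",
    "perturb_voxels",
]


class GenerationError(RuntimeError):
    """Raised when lateral placement keeps colliding; try a sparser spec."""


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Distributional description of one root system.

    lateral_count_mean is a Poisson mean; lateral length is normal
    (mean, sd) truncated at a minimum of 3 voxels; insertion_depth_range is
    the fraction of the primary axis where laterals may emerge; soil angle is
    normal (mean, sd) degrees from horizontal, clipped to [0, 89]; tortuosity
    is the per-step probability of a one-voxel sideways jitter of the primary
    axis.
    """

    primary_length: int = 80
    lateral_count_mean: float = 6.0
    lateral_count_fixed: int | None = None   # degenerate count distribution
    lateral_length_mean: float = 25.0
    lateral_length_sd: float = 6.0
    insertion_depth_range: tuple[float, float] = (0.05, 0.85)
    soil_angle_mean: float = 45.0
    soil_angle_sd: float = 15.0
    tortuosity: float = 0.1
    spacing: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.primary_length < 8 or self.lateral_length_mean < 1:
            raise ValueError("primary_length must be >= 8, lateral length >= 1")
        if not (0 <= self.soil_angle_mean <= 90):
            raise ValueError("soil angle must be in [0, 90] degrees")
        if not (0 <= self.tortuosity < 1):
            raise ValueError("tortuosity must be in [0, 1)")
        lo, hi = self.insertion_depth_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("insertion_depth_range must be a subinterval of [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows about the root it built."""

    tip_count: int
    branch_lengths: tuple        # rasterized Euclidean path length per branch
    insertion_depths: tuple      # z of each lateral's insertion vertex
    soil_angles: tuple           # degrees from horizontal per lateral

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "branch": [f"lateral{i + 1}" for i in range(len(self.soil_angles))],
            "length": self.branch_lengths[1:],
            "insertion_depth": self.insertion_depths,
            "soil_angle": self.soil_angles,
        })


_CHEB_OFFSETS = [np.array(o) - 1 for o in np.ndindex(3, 3, 3)
                 if o != (1, 1, 1)]


def _near(occupied: set, c: np.ndarray) -> list:
    """Occupied lattice points within Chebyshev distance 1 of c."""
    hits = []
    for off in _CHEB_OFFSETS:
        t = tuple(int(x) for x in (c + off))
        if t in occupied:
            hits.append(t)
    return hits


def _digital_line(start: np.ndarray, direction: np.ndarray, n_steps: int) -> np.ndarray:
    """26-connected digital line of n_steps voxels after ``start``.

    The dominant axis of ``direction`` advances by one voxel every step; the
    other two axes follow by error accumulation (clipped to one voxel per
    step).  Dominant-axis monotonicity makes the path a simple arc: voxels
    more than one step apart differ by at least 2 on that axis.
    """
    direction = np.asarray(direction, dtype=float)
    dom = int(np.argmax(np.abs(direction)))
    if direction[dom] == 0:
        raise ValueError("direction must be nonzero")
    ratios = direction / abs(direction[dom])
    pos = start.astype(float)
    cell = start.copy()
    out = np.empty((n_steps, 3), dtype=np.int64)
    for k in range(n_steps):
        pos = pos + ratios
        step = np.zeros(3, dtype=np.int64)
        step[dom] = int(np.sign(ratios[dom]))
        for ax in range(3):
            if ax != dom:
                step[ax] = int(np.clip(round(pos[ax] - cell[ax]), -1, 1))
        cell = cell + step
        out[k] = cell
        pos[dom] = cell[dom]
    return out


def _path_length(path: np.ndarray, spacing: float) -> float:
    if path.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1))) * spacing


_SIDE_DIRS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=np.int64)


def generate_root(spec: SyntheticRootSpec) -> tuple[VoxelSet, GroundTruth]:
    """Rasterize one root system; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    L = spec.primary_length

    if spec.lateral_count_fixed is not None:
        n_laterals = int(spec.lateral_count_fixed)
        rng.poisson(spec.lateral_count_mean)  # keep the draw order stable
    else:
        n_laterals = int(rng.poisson(spec.lateral_count_mean))
    lo, hi = spec.insertion_depth_range
    ins_lo = max(2, int(lo * L))
    ins_hi = min(L - 3, max(ins_lo + 1, int(hi * L)))

    # insertion indices spaced >= 3 apart so corners do not interfere
    candidates = np.arange(ins_lo, ins_hi)
    rng.shuffle(candidates)
    insertions: list[int] = []
    for c in candidates:
        if len(insertions) == n_laterals:
            break
        if all(abs(c - i) >= 3 for i in insertions):
            insertions.append(int(c))
    if len(insertions) < n_laterals:
        raise GenerationError(
            f"primary axis of length {L} cannot host {n_laterals} laterals; "
            "use a longer primary or fewer laterals"
        )
    insertions.sort()
    side_of = {i: _SIDE_DIRS[rng.integers(0, 4)] for i in insertions}
    guard = {j for i in insertions for j in range(i - 2, i + 3)}

    # primary axis: one +z step per voxel; forced sideways bend at each
    # insertion corner, optional random jitter elsewhere (suppressed near
    # corners so the attachment geometry stays clean)
    primary = [np.zeros(3, dtype=np.int64)]
    for k in range(1, L):
        step = np.array([0, 0, 1], dtype=np.int64)
        if k in side_of:
            step[:2] = side_of[k]
        elif k not in guard and rng.random() < spec.tortuosity:
            ax = int(rng.integers(0, 2))
            step[ax] = int(rng.choice([-1, 1]))
        primary.append(primary[-1] + step)
    primary = np.asarray(primary)
    occupied = {tuple(int(x) for x in c) for c in primary}
    branch_paths = [primary]
    insertion_depths, soil_angles = [], []

    # corner attachment voxels (one step past each bend, one voxel up) are
    # reserved so earlier laterals cannot wander next to a later insertion
    w_of = {i: primary[i] + np.array([side_of[i][0], side_of[i][1], -1],
                                     dtype=np.int64)
            for i in insertions}
    protected = {tuple(int(x) for x in w) for w in w_of.values()}

    for i in insertions:
        base = primary[i]
        side = side_of[i]
        w = w_of[i]
        blocked = occupied | (protected - {tuple(int(x) for x in w)})
        if _near(occupied, w) != [tuple(int(x) for x in base)]:
            raise GenerationError(
                "insertion corner is blocked; increase spacing between laterals"
            )
        placed = False
        for _attempt in range(60):
            angle = float(np.clip(rng.normal(spec.soil_angle_mean,
                                             spec.soil_angle_sd), 0.0, 89.0))
            azim0 = math.atan2(side[1], side[0])
            azim = azim0 + float(rng.uniform(-0.6, 0.6))
            theta = math.radians(angle)
            direction = np.array([
                math.cos(theta) * math.cos(azim),
                math.cos(theta) * math.sin(azim),
                math.sin(theta),
            ])
            length = max(3, int(round(rng.normal(spec.lateral_length_mean,
                                                 spec.lateral_length_sd))))
            # short outward stub clears the primary before the angled segment
            w2 = w + np.array([side[0], side[1], 1], dtype=np.int64)
            tail = _digital_line(w2, direction, max(1, length - 2))
            path = np.vstack([w[None, :], w2[None, :], tail])
            if _lateral_ok(path, base, occupied, blocked):
                occupied.update(tuple(int(x) for x in c) for c in path)
                branch_paths.append(np.vstack([base[None, :], path]))
                insertion_depths.append(int(base[2]))
                soil_angles.append(angle)
                placed = True
                break
        if not placed:
            raise GenerationError(
                "could not place a lateral without collisions; "
                "use a sparser spec (fewer/shorter laterals)"
            )

    coords = np.array(sorted(occupied), dtype=np.int64)
    vs = VoxelSet(coords, spacing=spec.spacing)
    truth = GroundTruth(
        tip_count=len(branch_paths),
        branch_lengths=tuple(_path_length(p, spec.spacing) for p in branch_paths),
        insertion_depths=tuple(insertion_depths),
        soil_angles=tuple(soil_angles),
    )
    return vs, truth


def _lateral_ok(path: np.ndarray, base: np.ndarray, occupied: set,
                blocked: set | None = None) -> bool:
    """A lateral may touch the existing root only at its insertion vertex.

    The first voxel must be adjacent to exactly one occupied voxel (the base);
    later voxels must be at Chebyshev distance >= 2 from everything already
    placed and from ``blocked`` (reserved corners of other insertions).  The
    path itself must be a simple arc (consecutive voxels adjacent,
    non-consecutive voxels not).  Together these keep cycle rank 0.
    """
    if blocked is None:
        blocked = occupied
    first = path[0]
    if tuple(int(x) for x in first) in occupied:
        return False
    if _near(occupied, first) != [tuple(int(x) for x in base)]:
        return False
    for c in path[1:]:
        if tuple(int(x) for x in c) in blocked or _near(blocked, c):
            return False
    # simple-arc check within the lateral (the stub joins two digital lines,
    # so verify globally rather than relying on dominant-axis monotonicity)
    diffs = np.abs(path[:, None, :] - path[None, :, :]).max(axis=2)
    k = np.abs(np.subtract.outer(np.arange(len(path)), np.arange(len(path))))
    if np.any(diffs[k == 1] != 1) or np.any(diffs[k > 1] < 2):
        return False
    return True


def make_population(n: int, spec_sampler=None, seed: int = 0):
    """Generate ``n`` independent roots with per-sample derived seeds.

    ``spec_sampler`` maps (sample index, rng) to a SyntheticRootSpec; by
    default all samples share the default spec (seeds still differ).  Returns
    the list of (VoxelSet, GroundTruth) pairs and a ground-truth summary table.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    master = np.random.default_rng(seed)
    roots, rows = [], []
    for k in range(n):
        # a fresh derived seed per regeneration attempt keeps samples
        # independent while absorbing occasional unplaceable laterals
        vs = truth = None
        for _ in range(20):
            sample_seed = int(master.integers(0, 2 ** 31 - 1))
            rng_k = np.random.default_rng(sample_seed)
            spec = (spec_sampler(k, rng_k) if spec_sampler is not None
                    else SyntheticRootSpec())
            spec = replace(spec, seed=sample_seed)
            try:
                vs, truth = generate_root(spec)
                break
            except GenerationError:
                continue
        if vs is None:
            raise GenerationError(f"sample {k}: generation kept failing")
        roots.append((vs, truth))
        rows.append({
            "sample_id": f"s{k:03d}",
            "tip_count": truth.tip_count,
            "total_length": sum(truth.branch_lengths),
            "mean_soil_angle": (float(np.mean(truth.soil_angles))
                                if truth.soil_angles else np.nan),
            "seed": spec.seed,
        })
    return roots, pd.DataFrame(rows)


def perturb_voxels(vs: VoxelSet, rate: float, seed: int = 0) -> VoxelSet:
    """Add boundary voxels and drop degree-1 voxels, preserving connectivity.

    Each empty lattice point adjacent to the root is added with probability
    ``rate``; each voxel with exactly one occupied neighbour is removed with
    probability ``rate`` (removing a leaf never disconnects the rest).
    Supports geometric-stability experiments.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return vs
    rng = np.random.default_rng(seed)
    occupied = {tuple(int(x) for x in c) for c in vs.coords}

    boundary = set()
    for c in vs.coords:
        for off in _CHEB_OFFSETS:
            t = tuple(int(x) for x in (c + off))
            if t not in occupied:
                boundary.add(t)
    additions = {t for t in sorted(boundary) if rng.random() < rate}
    occupied |= additions

    leaves = [t for t in sorted(occupied)
              if len(_near(occupied, np.array(t))) == 1]
    for t in leaves:
        if len(occupied) > 1 and rng.random() < rate:
            occupied.discard(t)

    coords = np.array(sorted(occupied), dtype=np.int64)
    return VoxelSet(coords, spacing=vs.spacing, depth_axis=vs.depth_axis)
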