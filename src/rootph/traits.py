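"""From distances and diagrams to trait vectors: G_PCs, GH_PCs and PDD_PCs.

The bottleneck-derived matrices are not Euclidean, so classical
multidimensional scaling first embeds the population (double-centred squared
distances, eigendecomposition, coordinates for positive eigenvalues); PCA on
the MDS scores returns the same coordinates but adds per-component variance
fractions, which drive how many components are retained.  Geodesic-only
embeddings give G_PCs, combined geodesic+depth embeddings give GH_PCs.

Independently, each geodesic persistence diagram is smoothed into a Gaussian
kernel density on a fixed grid; the flattened density vectors across the
population are run through PCA to give PDD_PCs.  PDD components use a higher
variance-retention cutoff because the density vectors concentrate variance in
very few directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtration import PersistenceBarcode, PersistenceDiagram, barcode_to_diagram
from .metrics import DistanceMatrix, pairwise_matrix

__all__ = [
    "EmbeddingResult",
    "KDEVector",
    "KDEGridSpec",
    "classical_mds",
    "pca",
    "select_num_pcs",
    "diagram_kde_vector",
    "compute_ph_traits",
    "PHTraitConfig",
]


class DegenerateInputError(ValueError):
    """Raised when an embedding has no positive-variance direction."""


@dataclass(frozen=True)
class EmbeddingResult:
    """Scores, per-component variance fractions, and (for MDS) eigenvalues."""

    scores: np.ndarray
    component_variances: np.ndarray
    eigenvalues: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class KDEGridSpec:
    """Evaluation grid for diagram densities; both bound endpoints are nodes."""

    lower: float = -20.0
    upper: float = 2000.0
    spacing: float = 20.0
    bandwidth: float = 20.0

    def __post_init__(self):
        if self.spacing <= 0 or self.bandwidth <= 0:
            raise ValueError("spacing and bandwidth must be positive")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")

    @property
    def nodes(self) -> np.ndarray:
        n = int(round((self.upper - self.lower) / self.spacing)) + 1
        return self.lower + self.spacing * np.arange(n)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class KDEVector:
    """Flattened grid of density values (row-major, birth axis fastest)."""

    values: np.ndarray
    grid: KDEGridSpec


def _fix_signs(scores: np.ndarray, loadings: np.ndarray | None = None):
    """Deterministic sign convention: per axis, make the largest-magnitude
    loading (or score when there are no loadings) positive; ties -> first index."""
    ref = loadings if loadings is not None else scores
    for k in range(scores.shape[1]):
        col = ref[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            scores[:, k] = -scores[:, k]
            if loadings is not None:
                loadings[:, k] = -loadings[:, k]
    return scores, loadings


def classical_mds(dm: DistanceMatrix | np.ndarray) -> EmbeddingResult:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres -1/2 * J D^2 J, eigendecomposes, and keeps coordinates for
    strictly positive eigenvalues (tolerance 1e-9 x max eigenvalue).  Scores
    are sorted by descending eigenvalue with a deterministic sign convention,
    and variance fractions are eigenvalues over the positive-eigenvalue total.
    """
    D = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise DegenerateInputError("no positive eigenvalue: all samples coincide")
    keep = eigval > 1e-9 * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = eigvec * np.sqrt(eigval)
    scores, _ = _fix_signs(scores)
    fractions = eigval / eigval.sum()
    return EmbeddingResult(scores, fractions, eigenvalues=eigval)


def pca(X: np.ndarray, standardize: bool = False) -> EmbeddingResult:
    """PCA by SVD of the (optionally standardized) column-centred data.

    Zero-variance features are dropped with a warning when standardizing.
    Variance fractions come from the squared singular values; the sign of each
    component makes its largest-magnitude loading positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D array with at least 2 samples")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s) "
                "before standardized PCA", stacklevel=2,
            )
            Xc = Xc[:, keep]
            sd = sd[keep]
        if Xc.shape[1] == 0:
            raise DegenerateInputError("all features have zero variance")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    if not np.any(keep):
        raise DegenerateInputError("data matrix has no variance")
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    scores = U * s
    loadings = Vt.T
    scores, _ = _fix_signs(scores, loadings)
    eigval = s ** 2 / (Xc.shape[0] - 1)
    fractions = eigval / eigval.sum()
    return EmbeddingResult(scores, fractions, eigenvalues=None)


def select_num_pcs(variance_fractions: np.ndarray, cumulative_threshold: float) -> int:
    """Smallest k whose cumulative variance fraction reaches the threshold."""
    fr = np.asarray(variance_fractions, dtype=float)
    if not (0 < cumulative_threshold <= 1):
        raise ValueError("cumulative_threshold must be in (0, 1]")
    cum = np.cumsum(fr)
    hit = np.flatnonzero(cum >= cumulative_threshold - 1e-12)
    if hit.size == 0:
        warnings.warn(
            f"threshold {cumulative_threshold} exceeds total variance "
            f"{cum[-1]:.6f}; keeping all components", stacklevel=2,
        )
        return len(fr)
    return int(hit[0]) + 1


def diagram_kde_vector(d, grid: KDEGridSpec | None = None, *,
                       bandwidth: float | None = None,
                       spacing: float | None = None,
                       bounds: tuple[float, float] | None = None) -> KDEVector:
    """Gaussian kernel density of a persistence diagram on a fixed grid.

    Each diagram point contributes a unit-mass isotropic bivariate normal with
    the given bandwidth; the estimate is their average, so vectors from
    diagrams of different sizes are comparable densities.  The default grid
    runs -20 to 2000 inclusive at spacing 20 on both the birth and death axes
    (102 nodes per axis, vector length 10404).  Flattening is row-major over
    (death, birth): the birth axis varies fastest.
    """
    if isinstance(d, PersistenceBarcode):
        d = barcode_to_diagram(d)
    pts = d.points if isinstance(d, PersistenceDiagram) else np.asarray(d, float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("diagram is empty")
    if grid is None:
        grid = KDEGridSpec()
    if bandwidth is not None or spacing is not None or bounds is not None:
        lo, hi = bounds if bounds is not None else (grid.lower, grid.upper)
        grid = KDEGridSpec(lo, hi,
                           spacing if spacing is not None else grid.spacing,
                           bandwidth if bandwidth is not None else grid.bandwidth)
    outside = ((pts < grid.lower) | (pts > grid.upper)).any(axis=1)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} diagram point(s) fall outside the KDE "
            "bounds; they still contribute mass", stacklevel=2,
        )
    nodes = grid.nodes
    bw = grid.bandwidth
    # separable kernels: density(b, d) = mean_i g(b - b_i) g(d - d_i)
    gb = np.exp(-0.5 * ((nodes[None, :] - pts[:, 0:1]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    gd = np.exp(-0.5 * ((nodes[None, :] - pts[:, 1:2]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    dens = np.einsum("id,ib->db", gd, gb) / pts.shape[0]
    return KDEVector(dens.ravel(), grid)


@dataclass(frozen=True)
class PHTraitConfig:
    """Variance-retention cutoffs and KDE grid for the PH trait vectors."""

    g_variance: float = 0.80
    gh_variance: float = 0.80
    pdd_variance: float = 0.95
    kde_grid: KDEGridSpec = KDEGridSpec()


def compute_ph_traits(population, sample_ids=None,
                      config: PHTraitConfig | None = None) -> pd.DataFrame:
    """The three persistent-homology trait families for a population.

    ``population`` is a sequence of (geodesic barcode, depth barcode) pairs.
    Returns a DataFrame indexed by sample id with columns G_PC1.., GH_PC1..
    (MDS then PCA of the geodesic-only and combined distance matrices, kept to
    their cumulative-variance cutoffs) and PDD_PC1.. (PCA of the geodesic
    diagram KDE vectors).
    """
    if config is None:
        config = PHTraitConfig()
    population = list(population)
    if len(population) < 3:
        raise ValueError("need at least 3 samples")
    if sample_ids is None:
        sample_ids = [f"s{k:03d}" for k in range(len(population))]

    dm_geo = pairwise_matrix(population, mode="geodesic", sample_ids=sample_ids)
    dm_gh = pairwise_matrix(population, mode="geodesic+depth", sample_ids=sample_ids)

    def mds_pcs(dm, threshold, prefix):
        emb = classical_mds(dm)
        emb = pca(emb.scores, standardize=False)
        k = select_num_pcs(emb.component_variances, threshold)
        return pd.DataFrame(
            emb.scores[:, :k], index=list(sample_ids),
            columns=[f"{prefix}{i + 1}" for i in range(k)],
        )

    g = mds_pcs(dm_geo, config.g_variance, "G_PC")
    gh = mds_pcs(dm_gh, config.gh_variance, "GH_PC")

    kde = np.vstack([
        diagram_kde_vector(geo, config.kde_grid).values for geo, _ in population
    ])
    emb = pca(kde, standardize=False)
    k = select_num_pcs(emb.component_variances, config.pdd_variance)
    pdd = pd.DataFrame(
        emb.scores[:, :k], index=list(sample_ids),
        columns=[f"PDD_PC{i + 1}" for i in range(k)],
    )
    out = pd.concat([g, gh, pdd], axis=1)
    out.index.name = "sample_id"
    return out
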