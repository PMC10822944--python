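"""Trait selection and downstream genetics statistics.

Collinearity among traits is pruned with the variance inflation factor,
VIF_j = 1/(1 - R_j^2) with R_j^2 from regressing trait j on all the others.
Rather than an arbitrary cutoff, the threshold comes from a data-driven rule:
sweep thresholds, record how many traits survive each, fit the curve
y = a*ln(x - b) + c, and define "high" VIF as the point where the fitted slope
equals 1 — the threshold past which relaxing it buys less than one trait per
unit of VIF.  That point is a + b in closed form; the "median" threshold is
half of it.

Also here: standardized PCA of the pruned trait table (mPCs), broad-sense
heritability H^2 = Vg / (Vg + Vr/nrep) from one-way variance components,
allele effect size estimate/mean(major allele), and transitive 1 Mb window
clustering of trait-associated SNPs into loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .traits import pca, select_num_pcs

__all__ = [
    "LogFitParams",
    "TASRecord",
    "vif_values",
    "vif_prune",
    "vif_threshold_sweep",
    "fit_log_curve",
    "high_vif_threshold",
    "median_vif_threshold",
    "multivariate_pcs",
    "heritability",
    "allele_effect_size",
    "colocalize_tas",
]

TRAIT_GROUPS = ("univariate", "PH", "multivariate")


@dataclass(frozen=True)
class LogFitParams:
    """Parameters of the threshold-sweep curve y = a*ln(x - b) + c."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class TASRecord:
    """One trait-associated SNP from an external association scan."""

    snp: str
    chrom: str
    pos: int
    trait: str
    group: str
    estimate: float = np.nan
    pvalue: float = np.nan

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("position must be non-negative")
        if self.group not in TRAIT_GROUPS:
            raise ValueError(f"group must be one of {TRAIT_GROUPS}")


def _trait_matrix(t: pd.DataFrame) -> pd.DataFrame:
    num = t.select_dtypes(include=[np.number])
    if num.columns.duplicated().any():
        raise ValueError("duplicate trait names")
    return num


def vif_values(t: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of every trait column.

    Each trait is regressed (with intercept) on all the others; exact
    collinearity is reported as +inf.  Requires more samples than traits for
    the OLS fits to be well posed.
    """
    X = _trait_matrix(t)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 traits")
    if n <= p:
        raise ValueError(
            f"{n} samples for {p} traits: too few for exact OLS; "
            "reduce the trait set first"
        )
    const = X.std(axis=0, ddof=1) == 0
    if const.any():
        raise ValueError(
            f"constant column(s) have undefined VIF: {list(X.columns[const])}"
        )
    vals = X.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(X.columns):
        y = vals[:, j]
        others = np.delete(vals, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ssr = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ssr / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_prune(t: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, list]:
    """Greedy removal of the worst-VIF trait until all VIF <= threshold.

    Ties go to the later column.  Returns the pruned table and a removal log
    of (trait, VIF-at-removal) pairs in removal order.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    X = _trait_matrix(t).copy()
    removed: list[tuple[str, float]] = []
    while X.shape[1] >= 2:
        vif = vif_values(X)
        worst = vif.max()
        if worst <= threshold:
            break
        # ties -> remove the later column
        idx = np.flatnonzero(vif.to_numpy() == worst)[-1]
        name = X.columns[idx]
        removed.append((name, float(worst)))
        X = X.drop(columns=[name])
    return X, removed


def vif_threshold_sweep(t: pd.DataFrame, thresholds) -> tuple[np.ndarray, np.ndarray]:
    """Remaining-trait counts over an increasing sequence of VIF thresholds."""
    thr = np.asarray(thresholds, dtype=float)
    if thr.size < 4:
        raise ValueError("need at least 4 thresholds")
    if np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    counts = np.array([vif_prune(t, x)[0].shape[1] for x in thr])
    return thr, counts


def _log_model(params, x):
    a, b, c = params
    return a * np.log(x - b) + c


def fit_log_curve(x, y) -> LogFitParams:
    """Nonlinear least squares fit of y = a*ln(x - b) + c to sweep data.

    The offset b is constrained below min(x).  Initialization: a0 spreads the
    y-range over the log of the x-range ratio, b0 = 0.9*min(x), c0 = mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    xmin = x.min()
    b0 = 0.9 * xmin
    span = np.ptp(y)
    ratio = (x.max() - b0) / (xmin - b0)
    a0 = span / np.log(ratio) if ratio > 1 else 1.0
    if span == 0:
        warnings.warn("constant y: logarithmic fit is degenerate", stacklevel=2)
    c0 = float(y.mean())
    # keep x - b strictly positive throughout the optimization
    b_upper = xmin - 1e-9 * max(1.0, abs(xmin))
    res = least_squares(
        lambda p: _log_model(p, x) - y,
        x0=[a0 if span else 0.0, min(b0, b_upper), c0],
        bounds=([-np.inf, -np.inf, -np.inf], [np.inf, b_upper, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500 * 3,
    )
    if not res.success:
        raise RuntimeError(
            f"logarithmic fit did not converge: {res.message}; "
            f"final residual norm {np.linalg.norm(res.fun):.3g}"
        )
    return LogFitParams(*map(float, res.x))


def high_vif_threshold(p: LogFitParams) -> float:
    """The 'high' VIF threshold: x where the fitted curve has slope 1.

    d/dx [a*ln(x-b)+c] = a/(x-b) = 1 gives x = a + b.
    """
    if p.a <= 0:
        raise ValueError("slope-1 point requires a > 0")
    return p.a + p.b


def median_vif_threshold(high: float) -> float:
    """Half the 'high' threshold (returned exactly, without rounding)."""
    if high <= 2:
        raise ValueError("high threshold must exceed 2")
    return high / 2.0


def multivariate_pcs(t: pd.DataFrame, cumulative_threshold: float = 0.90) -> pd.DataFrame:
    """Standardized PCA of the (pruned) trait table; components named mPC1..k.

    Keeps the smallest number of components whose cumulative variance reaches
    the threshold (default 90%).
    """
    X = _trait_matrix(t)
    emb = pca(X.to_numpy(dtype=float), standardize=True)
    k = select_num_pcs(emb.component_variances, cumulative_threshold)
    return pd.DataFrame(
        emb.scores[:, :k], index=t.index,
        columns=[f"mPC{i + 1}" for i in range(k)],
    )


def heritability(values, genotypes) -> float:
    """Broad-sense heritability H^2 = Vg / (Vg + Vr/nrep).

    Variance components come from a one-way random-effects decomposition by
    the method of moments: Vr is the within-genotype mean square, Vg is
    (between MS - within MS) / n0 with n0 the effective replicate number for
    unbalanced designs, floored at 0.  nrep is the arithmetic mean number of
    replicates per genotype.
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    if values.shape[0] != genotypes.shape[0]:
        raise ValueError("values and genotypes must align")
    labels, inverse = np.unique(genotypes, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("heritability undefined for a single genotype")
    N = values.size
    counts = np.bincount(inverse)
    means = np.bincount(inverse, weights=values) / counts
    grand = values.mean()
    ss_within = float(np.sum((values - means[inverse]) ** 2))
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    df_within = N - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_between = ss_between / (k - 1)
    # effective replicate number for unbalanced one-way designs
    n0 = (N - np.sum(counts ** 2) / N) / (k - 1)
    vg = max((ms_between - ms_within) / n0, 0.0)
    vr = ms_within
    nrep = N / k
    denom = vg + vr / nrep
    return float(vg / denom) if denom > 0 else 0.0


def allele_effect_size(estimate: float, major_allele_values) -> float:
    """Effect size = estimate / mean(major-allele trait values).

    Positive values mean the major allele increases the trait; negative values
    mean the minor allele does.
    """
    mean = float(np.mean(np.asarray(major_allele_values, dtype=float)))
    if mean == 0:
        raise ValueError("major-allele mean is zero; effect size undefined")
    return float(estimate) / mean


@dataclass(frozen=True)
class Locus:
    """A cluster of trait-associated SNPs within a genomic window."""

    chrom: str
    start: int
    end: int
    records: tuple = field(default=())

    @property
    def groups(self) -> frozenset:
        return frozenset(r.group for r in self.records)


def colocalize_tas(records, window: int = 1_000_000):
    """Merge trait-associated SNPs within ``window`` bp into loci, transitively.

    On each chromosome, SNPs whose positions are within the window of each
    other chain into a single locus (so three SNPs at 0, 0.9 Mb and 1.8 Mb
    form one locus under the default 1 Mb window).  Returns the locus list and
    a Venn count dict mapping each sorted group-combination (e.g.
    ``("PH", "univariate")``) to the number of loci containing exactly those
    trait groups.
    """
    records = list(records)
    loci: list[Locus] = []
    by_chrom: dict[str, list[TASRecord]] = {}
    for r in records:
        by_chrom.setdefault(str(r.chrom), []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.pos, r.snp))
        cluster = [rs[0]]
        for r in rs[1:]:
            if r.pos - cluster[-1].pos <= window:
                cluster.append(r)
            else:
                loci.append(_make_locus(chrom, cluster))
                cluster = [r]
        loci.append(_make_locus(chrom, cluster))
    venn: dict[tuple, int] = {}
    for locus in loci:
        key = tuple(sorted(locus.groups))
        venn[key] = venn.get(key, 0) + 1
    return loci, venn


def _make_locus(chrom: str, cluster: list) -> Locus:
    return Locus(chrom, cluster[0].pos, cluster[-1].pos, tuple(cluster))
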