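"""End-to-end orchestration: voxels in, trait tables and statistics out.

A :class:`PipelineConfig` holds every tunable of the workflow with defaults
matching the published analysis (unit voxel spacing, filtration step 1, KDE
bandwidth/spacing 20 on [-20, 2000]^2, variance retention 80/80/95/90%, VIF
threshold from the log-fit rule, 1 Mb co-localization window).  ``run_pipeline``
executes the stages in order, writing every intermediate table as CSV plus a
JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filtration import depth_function, geodesic_function, h0_barcode
from .metrics import pairwise_matrix
from .synthetic import SyntheticRootSpec, make_population
from .stats import (heritability, median_vif_threshold, high_vif_threshold,
                    fit_log_curve, multivariate_pcs, vif_prune,
                    vif_threshold_sweep)
from .traits import KDEGridSpec, PHTraitConfig, compute_ph_traits
from .voxels import (VoxelSet, build_network, cycle_rank, largest_component,
                     read_voxel_coords, read_voxel_ply)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults are the published analysis settings."""

    inputs: list = field(default_factory=list)   # PLY/CSV paths; empty = simulate
    spacing: float = 1.0
    top_selector: str = "auto"
    filtration_step: float = 1.0
    kde_bandwidth: float = 20.0
    kde_bounds: tuple = (-20.0, 2000.0)
    kde_spacing: float = 20.0
    g_variance: float = 0.80
    gh_variance: float = 0.80
    pdd_variance: float = 0.95
    mpc_variance: float = 0.90
    vif_mode: str = "fixed"          # fixed | log-fit-high | log-fit-median
    vif_threshold: float = 8.0       # used when vif_mode == "fixed"
    vif_sweep: tuple = (2.0, 50.0, 0.5)  # (start, stop, step) for log-fit modes
    window_bp: int = 1_000_000
    n_simulate: int = 20
    n_genotypes: int = 10
    seed: int = 0
    univariate_csv: str | None = None
    out_dir: str = "rootph_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = [str(p) for p in d["inputs"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("kde_bounds", "vif_sweep"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_voxels(path, spacing: float = 1.0) -> VoxelSet:
    """Dispatch on extension: .ply or coordinate .csv."""
    p = Path(path)
    if p.suffix.lower() == ".ply":
        return read_voxel_ply(p, spacing=spacing)
    return read_voxel_coords(p, spacing=spacing)


def barcodes_for_voxels(vs: VoxelSet, top="auto", step: float = 1.0):
    """Largest component -> geodesic and depth H0 barcodes."""
    net = largest_component(build_network(vs))
    rank = cycle_rank(net)
    if rank:
        logger.warning("network has cycle rank %d (not tree-structured)", rank)
    geo = h0_barcode(net, geodesic_function(net, top=top), step=step)
    dep = h0_barcode(net, depth_function(net), step=step)
    return geo, dep


def barcodes_frame(pairs, sample_ids) -> pd.DataFrame:
    rows = []
    for sid, (geo, dep) in zip(sample_ids, pairs):
        for bc in (geo, dep):
            for birth, death in bc.bars:
                rows.append((sid, bc.function, birth, death))
    return pd.DataFrame(rows, columns=["sample_id", "function", "birth", "death"])


def _default_spec_sampler(n_genotypes: int, nrep: int):
    """Per-genotype architecture parameters; replicates share them.

    Genotypes differ in lateral count, lateral length and soil angle — the
    genetic signal — while per-replicate seeds supply within-genotype noise.
    """

    def sampler(k: int, rng: np.random.Generator) -> SyntheticRootSpec:
        g = k // nrep
        geno_rng = np.random.default_rng(100_000 + g)
        return SyntheticRootSpec(
            primary_length=70,
            lateral_count_mean=float(geno_rng.uniform(2, 9)),
            lateral_length_mean=float(geno_rng.uniform(15, 30)),
            lateral_length_sd=4.0,
            soil_angle_mean=float(geno_rng.uniform(15, 70)),
            soil_angle_sd=8.0,
            tortuosity=0.08,
        )

    return sampler


def _float_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format="%.12g")


def _cap_traits(table: pd.DataFrame, n_samples: int, margin: int = 5):
    """Trim trailing components so collinearity regressions stay well posed.

    Principal-component families are ordered by decreasing variance, so when
    the merged table has too many columns for n_samples the cheapest columns
    to sacrifice are each family's trailing components.  Drops one trailing
    column at a time from the currently largest family until at most
    n_samples - margin columns remain; returns the reduced table and the
    dropped column names.
    """
    pattern = re.compile(r"^(.*?)(\d+)$")
    table = table.copy()
    dropped: list[str] = []
    while table.shape[1] > max(2, n_samples - margin):
        families: dict[str, list[str]] = {}
        for col in table.columns:
            m = pattern.match(col)
            families.setdefault(m.group(1) if m else col, []).append(col)
        fam = max(families, key=lambda f: (len(families[f]),
                                           list(families).index(f)))
        victim = max(families[fam],
                     key=lambda c: int(pattern.match(c).group(2))
                     if pattern.match(c) else -1)
        dropped.append(victim)
        table = table.drop(columns=[victim])
    return table, dropped


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of output paths and key tables.

    In simulate mode (no input files) a synthetic population with genotype
    replicate structure is generated from ``cfg.seed``.  Stage order: voxels ->
    barcodes -> distance matrices -> PH traits -> merged trait table -> VIF
    pruning -> mPCs -> heritability -> manifest.  Any stage error is re-raised
    as :class:`PipelineError` naming the stage, after writing a FAILED marker.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"out_dir": str(out)}
    stage = "setup"
    try:
        # --- stage: voxels ---------------------------------------------------
        stage = "voxels"
        genotypes = None
        if cfg.inputs:
            voxel_sets = [load_voxels(p, cfg.spacing) for p in cfg.inputs]
            sample_ids = [Path(p).stem for p in cfg.inputs]
            truth_table = None
        else:
            nrep = max(1, cfg.n_simulate // cfg.n_genotypes)
            roots, truth_table = make_population(
                cfg.n_simulate,
                spec_sampler=_default_spec_sampler(cfg.n_genotypes, nrep),
                seed=cfg.seed,
            )
            voxel_sets = [vs for vs, _ in roots]
            sample_ids = list(truth_table["sample_id"])
            genotypes = [f"g{(k // nrep):02d}" for k in range(cfg.n_simulate)]
            _float_csv(truth_table, out / "ground_truth.csv", index=False)
        if len(voxel_sets) < 3:
            raise ValueError("need at least 3 samples")

        # --- stage: barcodes -------------------------------------------------
        stage = "barcodes"
        pairs = [barcodes_for_voxels(vs, top=cfg.top_selector,
                                     step=cfg.filtration_step)
                 for vs in voxel_sets]
        _float_csv(barcodes_frame(pairs, sample_ids), out / "barcodes.csv",
                   index=False)

        # --- stage: distances ------------------------------------------------
        stage = "distances"
        dm_geo = pairwise_matrix(pairs, mode="geodesic", sample_ids=sample_ids)
        dm_gh = pairwise_matrix(pairs, mode="geodesic+depth", sample_ids=sample_ids)
        _float_csv(dm_geo.to_frame(), out / "distance_geodesic.csv")
        _float_csv(dm_gh.to_frame(), out / "distance_geodesic_depth.csv")

        # --- stage: traits ---------------------------------------------------
        stage = "traits"
        grid = KDEGridSpec(cfg.kde_bounds[0], cfg.kde_bounds[1],
                           cfg.kde_spacing, cfg.kde_bandwidth)
        ph_cfg = PHTraitConfig(cfg.g_variance, cfg.gh_variance,
                               cfg.pdd_variance, grid)
        ph_traits = compute_ph_traits(pairs, sample_ids=sample_ids, config=ph_cfg)
        _float_csv(ph_traits, out / "ph_traits.csv")
        (out / "kde_grid.json").write_text(json.dumps(
            dataclasses.asdict(grid), indent=2, sort_keys=True) + "\n")

        # --- stage: merge ----------------------------------------------------
        stage = "merge"
        merged = ph_traits.copy()
        if cfg.univariate_csv:
            uni = pd.read_csv(cfg.univariate_csv).set_index("sample_id")
            unmatched = sorted(set(uni.index) ^ set(merged.index))
            if unmatched:
                logger.warning("unmatched sample ids in univariate table: %s",
                               unmatched)
            merged = merged.join(uni, how="left")
        _float_csv(merged, out / "traits_merged.csv")

        # --- stage: select ---------------------------------------------------
        stage = "select"
        merged_for_vif, capped = _cap_traits(merged, len(sample_ids))
        if capped:
            logger.warning(
                "dropped %d trailing low-variance components before VIF so "
                "the collinearity regressions keep residual degrees of "
                "freedom: %s", len(capped), capped)
        vif_meta: dict = {"mode": cfg.vif_mode, "pre_reduced": capped}
        if cfg.vif_mode == "fixed":
            threshold = cfg.vif_threshold
        else:
            start, stop, step = cfg.vif_sweep
            thr = np.arange(start, stop + step / 2, step)
            x, y = vif_threshold_sweep(merged_for_vif, thr)
            params = fit_log_curve(x, y)
            high = high_vif_threshold(params)
            threshold = (high if cfg.vif_mode == "log-fit-high"
                         else median_vif_threshold(high))
            vif_meta.update(fit=dataclasses.asdict(params), high=high,
                            note="published analysis rounded the median "
                                 "threshold to 8")
            _float_csv(pd.DataFrame({"threshold": x, "n_traits": y}),
                       out / "vif_sweep.csv", index=False)
        vif_meta["threshold"] = float(threshold)
        pruned, removed = vif_prune(merged_for_vif, threshold)
        vif_meta["removed"] = [name for name, _ in removed]
        _float_csv(pruned, out / "traits_pruned.csv")
        (out / "vif_log.txt").write_text(
            "".join(f"removed {name} (VIF={v:.6g})\n" for name, v in removed))
        (out / "vif_meta.json").write_text(
            json.dumps(vif_meta, indent=2, sort_keys=True) + "\n")

        # --- stage: mpcs -----------------------------------------------------
        stage = "mpcs"
        mpcs = multivariate_pcs(pruned, cfg.mpc_variance)
        _float_csv(mpcs, out / "mpcs.csv")

        # --- stage: heritability --------------------------------------------
        stage = "heritability"
        if genotypes is not None:
            table = pd.concat([merged, mpcs], axis=1)
            h2 = pd.Series(
                {col: heritability(table[col].to_numpy(), genotypes)
                 for col in table.columns}, name="H2")
            h2.index.name = "trait"
            _float_csv(h2.to_frame(), out / "heritability.csv")
            artifacts["heritability"] = h2

        # --- stage: manifest -------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": cfg.to_dict(),
            "rootph_version": __version__,
            "n_samples": len(sample_ids),
            "sample_ids": sample_ids,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    artifacts.update(
        ph_traits=ph_traits, merged=merged, pruned=pruned, mpcs=mpcs,
        distance_geodesic=dm_geo, distance_combined=dm_gh,
    )
    return artifacts
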