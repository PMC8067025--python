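"""Occurrence preprocessing: spatial thinning, background points, VIF screening.

Spatial thinning enforces a minimum pairwise distance between occurrence
records (default: the 682 m home-range radius) to reduce spatial
autocorrelation from transect surveys. Background (pseudo-absence) points are
drawn uniformly over unmasked cells inside a study polygon. Collinear
covariates are removed stepwise on the variance inflation factor with the
conventional cutoff of 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridSpec, OccurrenceSet, PointLabel, StudyRegion

VIF_INF = math.inf


@dataclass(frozen=True)
class ThinningConfig:
    min_distance: float = 682.0
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


@dataclass(frozen=True)
class VifConfig:
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.cutoff <= 1:
            raise ValueError("VIF cutoff must exceed 1")


@dataclass
class BackgroundConfig:
    n_points: int = 50
    region: StudyRegion | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be positive")


def _one_thin_pass(xy: np.ndarray, min_distance: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Randomized greedy pass: repeatedly delete one point, chosen uniformly
    among those with the most conflicting neighbours, until conflict-free.
    Returns the boolean keep mask."""
    keep = np.ones(len(xy), dtype=bool)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(min_distance, output_type="ndarray")
    # strictly-closer-than min_distance conflicts; points exactly at the
    # minimum distance are allowed (retained points must be >= apart)
    if pairs.size:
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_distance]
    counts = np.zeros(len(xy), dtype=int)
    np.add.at(counts, pairs.ravel(), 1)
    alive_pairs = pairs
    while counts.max(initial=0) > 0:
        worst = np.flatnonzero(counts == counts.max())
        victim = rng.choice(worst)
        keep[victim] = False
        hit = (alive_pairs[:, 0] == victim) | (alive_pairs[:, 1] == victim)
        for a, b in alive_pairs[hit]:
            counts[a] -= 1
            counts[b] -= 1
        counts[victim] = 0
        alive_pairs = alive_pairs[~hit]
    return keep


def spatial_thin(pts: OccurrenceSet, cfg: ThinningConfig) -> OccurrenceSet:
    """Thin points so all retained pairs are >= min_distance apart.

    Runs ``n_repeats`` seeded randomized greedy passes and returns the repeat
    retaining the most points (first such repeat on ties); deterministic for
    a given seed. The output is always a non-empty subset of the input.
    """
    if len(pts) == 0:
        raise ValueError("cannot thin an empty point set")
    best: np.ndarray | None = None
    ss = np.random.SeedSequence(cfg.seed)
    for child in ss.spawn(cfg.n_repeats):
        rng = np.random.default_rng(child)
        keep = _one_thin_pass(pts.xy, cfg.min_distance, rng)
        if best is None or keep.sum() > best.sum():
            best = keep
    return pts.subset(best)


def sample_background(
    cfg: BackgroundConfig,
    grid: GridSpec,
    nodata_mask: np.ndarray | None = None,
) -> OccurrenceSet:
    """Uniform background points over unmasked cell centres inside the region.

    Cells are drawn without replacement; points sit at cell centres.
    Deterministic for a given seed.
    """
    if nodata_mask is None:
        nodata_mask = np.zeros(grid.shape, dtype=bool)
    gx, gy = grid.centre_mesh()
    candidate = ~nodata_mask
    if cfg.region is not None:
        inside = cfg.region.contains_points(gx.ravel(), gy.ravel())
        candidate &= inside.reshape(grid.shape)
    idx = np.flatnonzero(candidate.ravel())
    if len(idx) < cfg.n_points:
        raise ValueError(
            f"only {len(idx)} candidate cells for {cfg.n_points} background points"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(idx, size=cfg.n_points, replace=False)
    xy = np.column_stack([gx.ravel()[chosen], gy.ravel()[chosen]])
    return OccurrenceSet(xy=xy, label=PointLabel.BACKGROUND)


def compute_vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor of every column.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from the least-squares regression of
    column j on all the other columns plus an intercept. A perfectly collinear
    column gets the +inf sentinel.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    if X.isna().any().any():
        raise ValueError("VIF input contains missing values")
    out: dict[str, float] = {}
    arr = X.to_numpy(float)
    n = arr.shape[0]
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[name] = VIF_INF  # constant column: degenerate
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[name] = VIF_INF
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


def vif_stepwise(X: pd.DataFrame, cfg: VifConfig | None = None
                 ) -> tuple[list[str], list[str]]:
    """Stepwise removal of the largest-VIF column while max VIF >= cutoff.

    The +inf sentinel sorts above every finite VIF; among ties the earliest
    column (in the original order) is removed first. Returns the retained
    names and the excluded names in removal order.
    """
    cfg = cfg or VifConfig()
    cols = list(X.columns)
    excluded: list[str] = []
    while len(cols) >= 2:
        vifs = compute_vif(X[cols])
        worst = max(vifs.values())
        if worst < cfg.cutoff:
            break
        victim = next(c for c in cols if vifs[c] == worst)
        cols.remove(victim)
        excluded.append(victim)
    return cols, excluded


def vif_report(X: pd.DataFrame, cfg: VifConfig | None = None) -> pd.DataFrame:
    """CSV-ready VIF screening report: variable, vif, excluded, step."""
    cfg = cfg or VifConfig()
    retained, excluded = vif_stepwise(X, cfg)
    final_vifs = compute_vif(X[retained]) if len(retained) >= 2 else \
        {c: float("nan") for c in retained}
    rows = []
    for name in X.columns:
        if name in excluded:
            rows.append({"variable": name, "vif": float("nan"),
                         "excluded": True, "step": excluded.index(name) + 1})
        else:
            rows.append({"variable": name, "vif": final_vifs[name],
                         "excluded": False, "step": 0})
    return pd.DataFrame(rows)
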