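"""Seeded synthetic landscapes, presence samples and carcass samples.

The generator emulates the covariate structure the habitat analysis expects:
smooth Gaussian-random-field terrain and land-cover classes, engineered
distance-to-feature and home-range focal-density layers, plus pure-noise
fields and near-duplicate collinear copies to exercise the VIF screen.

The default ground truth makes habitat suitability increase with distance to
agricultural fields, coniferous focal density and distance to trails (the
directions the habitat model is expected to recover); carcass samples can add
a south-east (135 degree) aspect preference on top of the same suitability,
emulating mortality concentrated on the preferred, sun-exposed slopes.

Everything is a pure function of the configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .covariates import (FeatureMask, HomeRangeWindow, distance_to_feature,
                         focal_density, terrain_derivatives)
from .grids import (GridSpec, OccurrenceSet, PointLabel,
                    RasterLayer, RasterStack, StudyRegion)

#: layer order of the default stack: 10 candidates + 2 collinear copies
DEFAULT_LAYERS = (
    "altitude", "slope", "aspect", "dist_field", "dist_trail", "dist_stream",
    "conifer_density", "broadleaf_density", "noise1", "noise2",
    "altitude_copy", "dist_stream_copy",
)


@dataclass(frozen=True)
class GeneratorConfig:
    grid: GridSpec = GridSpec(cell_size=30.0, origin=(0.0, 6000.0),
                              n_rows=200, n_cols=200, crs_id="synthetic-utm")
    smoothing_sigma: float = 10.0  # cells; scale of landscape autocorrelation
    true_betas: Mapping[str, float] = field(default_factory=lambda: {
        "dist_field": 3.0, "conifer_density": 2.4, "dist_trail": 1.8,
    })
    beta0: float = -6.0
    n_presence: int = 150
    n_carcass: int = 24
    collinear_copies: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "altitude_copy": ("altitude", 0.3),
            "dist_stream_copy": ("dist_stream", 0.3),
        })
    window: HomeRangeWindow = HomeRangeWindow()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presence < 1:
            raise ValueError("n_presence must be positive")
        for beta in self.true_betas.values():
            if not np.isfinite(beta):
                raise ValueError("true betas must be finite")


@dataclass
class TruthRecord:
    """Ground truth behind a generated landscape."""

    suitability: RasterLayer
    informative: list[str]
    betas: dict[str, float]
    beta0: float
    config: GeneratorConfig


def _smooth_field(grid: GridSpec, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma,
                        mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(cfg: GeneratorConfig | None = None
                       ) -> tuple[RasterStack, TruthRecord]:
    """Build the covariate stack and its ground-truth suitability."""
    cfg = cfg or GeneratorConfig()
    grid = cfg.grid
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(10)]

    dem_field = _smooth_field(grid, cfg.smoothing_sigma, rngs[0])
    dem = RasterLayer("altitude", grid, 700.0 + 250.0 * dem_field)
    terrain = terrain_derivatives(dem)

    f_field = _smooth_field(grid, cfg.smoothing_sigma, rngs[1])
    f_trail = _smooth_field(grid, cfg.smoothing_sigma, rngs[2])
    f_conifer = _smooth_field(grid, cfg.smoothing_sigma, rngs[3])
    f_broad = _smooth_field(grid, cfg.smoothing_sigma, rngs[4])
    f_stream = _smooth_field(grid, cfg.smoothing_sigma, rngs[5])

    masks = {
        "field": f_field > np.quantile(f_field, 0.95),
        "trail": np.abs(f_trail) < np.quantile(np.abs(f_trail), 0.04),
        "conifer": f_conifer > np.quantile(f_conifer, 0.55),
        "broadleaf": f_broad > np.quantile(f_broad, 0.60),
        "stream": np.abs(f_stream) < np.quantile(np.abs(f_stream), 0.03),
    }
    feature = {k: FeatureMask(grid, v) for k, v in masks.items()}

    layers = {
        "altitude": dem,
        "slope": terrain["slope"],
        "aspect": terrain["aspect"],
        "dist_field": distance_to_feature(feature["field"], "dist_field"),
        "dist_trail": distance_to_feature(feature["trail"], "dist_trail"),
        "dist_stream": distance_to_feature(feature["stream"], "dist_stream"),
        "conifer_density": focal_density(feature["conifer"], cfg.window,
                                         "conifer_density"),
        "broadleaf_density": focal_density(feature["broadleaf"], cfg.window,
                                           "broadleaf_density"),
        "noise1": RasterLayer("noise1", grid,
                              _smooth_field(grid, cfg.smoothing_sigma,
                                            rngs[6])),
        "noise2": RasterLayer("noise2", grid,
                              _smooth_field(grid, cfg.smoothing_sigma,
                                            rngs[7])),
    }
    copy_rng = rngs[8]
    for new_name, (source, noise_sd) in cfg.collinear_copies.items():
        src = layers[source]
        sd = src.valid_values().std()
        vals = src.values + noise_sd * sd * copy_rng.standard_normal(grid.shape)
        layers[new_name] = RasterLayer(new_name, grid, vals,
                                       mask=src.mask.copy())
    stack = RasterStack([layers[n] for n in layers])

    nodata = stack.combined_mask()
    eta = np.full(grid.shape, cfg.beta0, dtype=float)
    for name, beta in cfg.true_betas.items():
        v = layers[name].values
        valid = v[~nodata]
        eta += beta * (v - valid.mean()) / valid.std()
    suit = RasterLayer("true_suitability", grid, expit(eta), mask=nodata)
    truth = TruthRecord(suitability=suit,
                        informative=list(cfg.true_betas),
                        betas=dict(cfg.true_betas), beta0=cfg.beta0,
                        config=cfg)
    return stack, truth


def sample_points(truth: TruthRecord, n: int, label: PointLabel | str,
                  seed: int = 0, aspect_bias: bool = False,
                  aspect_layer: RasterLayer | None = None,
                  aspect_mu: float = 135.0, aspect_kappa: float = 2.0,
                  region: StudyRegion | None = None) -> OccurrenceSet:
    """Draw points with cell probability proportional to true suitability.

    With ``aspect_bias`` the weight is multiplied by a von-Mises-style factor
    ``exp(kappa * cos(theta - mu))`` centred on the south-east (135 degrees).
    Cells are drawn without replacement; each point sits at its cell centre
    plus a small seeded jitter (< half a cell). Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be positive")
    grid = truth.suitability.grid
    w = np.where(truth.suitability.mask, 0.0, truth.suitability.values)
    if aspect_bias:
        if aspect_layer is None:
            raise ValueError("aspect_bias requires an aspect layer")
        theta = np.radians(aspect_layer.values)
        factor = np.exp(aspect_kappa * np.cos(theta - np.radians(aspect_mu)))
        factor[aspect_layer.mask] = np.exp(-aspect_kappa)  # flat cells: worst
        w = w * factor
    if region is not None:
        gx, gy = grid.centre_mesh()
        inside = region.contains_points(gx.ravel(), gy.ravel())
        w = w * inside.reshape(grid.shape)
    flat = w.ravel()
    ok = flat > 0
    if ok.sum() < n:
        raise ValueError(f"only {int(ok.sum())} candidate cells for {n} points")
    rng = np.random.default_rng(seed)
    # Gumbel top-k trick: weighted sampling without replacement
    keys = np.full(flat.shape, -np.inf)
    keys[ok] = np.log(flat[ok]) + rng.gumbel(size=int(ok.sum()))
    chosen = np.argpartition(-keys, n - 1)[:n]
    rows, cols = np.unravel_index(chosen, grid.shape)
    cx = grid.x_centres()[cols]
    cy = grid.y_centres()[rows]
    jitter = rng.uniform(-0.49, 0.49, size=(n, 2)) * grid.cell_size
    xy = np.column_stack([cx, cy]) + jitter
    return OccurrenceSet(xy=xy, label=PointLabel(label))
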