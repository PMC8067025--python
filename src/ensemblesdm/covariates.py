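"""Engineered environmental layers: distances, focal densities, terrain.

These are the derived covariates a habitat analysis builds from categorical
land-cover maps and a DEM: Euclidean distance to the nearest cell of a feature
class (fields, trails, streams, ...), the total area of a feature class within
a circular moving window sized to the species' home range, and slope/aspect
from the elevation model.

All distances are centre-to-centre. The default home-range window is the
male long-tailed goral home range: 1.46 km^2, radius 682 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec, LayerKind, RasterLayer


@dataclass(frozen=True)
class HomeRangeWindow:
    """Circular focal window; defaults to the male goral home range."""

    radius: float = 682.0      # metres
    area: float = 1.46e6       # m^2, reference value

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if abs(np.pi * self.radius**2 - self.area) > 0.01 * self.area:
            raise ValueError(
                "window radius and area disagree by more than 1% "
                f"(pi*r^2 = {np.pi * self.radius ** 2:.0f}, area = {self.area:.0f})"
            )


@dataclass
class FeatureMask:
    """Boolean membership of each cell in one feature class."""

    grid: GridSpec
    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("feature mask shape does not match its grid")

    @classmethod
    def from_layer(cls, layer: RasterLayer, class_value: float) -> "FeatureMask":
        member = (layer.values == class_value) & ~layer.mask
        return cls(grid=layer.grid, member=member)


def distance_to_feature(mask: FeatureMask, name: str = "distance") -> RasterLayer:
    """Euclidean distance (m) from each cell centre to the nearest feature cell.

    Feature cells score 0. Raises if the feature class is empty.
    """
    if not mask.member.any():
        raise ValueError(f"feature mask for {name!r} has no member cells")
    dist = ndimage.distance_transform_edt(
        ~mask.member, sampling=mask.grid.cell_size
    )
    return RasterLayer(name=name, grid=mask.grid, values=dist,
                       kind=LayerKind.CONTINUOUS)


def _disk_kernel(radius: float, cell_size: float) -> np.ndarray:
    # offsets whose centre distance is within the closed ball of the radius
    r_cells = int(np.floor(radius / cell_size))
    di = np.arange(-r_cells, r_cells + 1)
    dd = (di[:, None] ** 2 + di[None, :] ** 2) * cell_size**2
    return (dd <= radius**2).astype(float)


def focal_density(mask: FeatureMask, window: HomeRangeWindow | None = None,
                  name: str = "density") -> RasterLayer:
    """Feature area (m^2) within the circular window around each cell centre.

    Counts feature-cell centres within ``window.radius`` of the focal centre
    and multiplies by the cell area. Near the grid edge the truncated window
    is used as-is (absolute m^2, no area normalisation), matching home-range
    density units of m^2 per window.
    """
    window = window or HomeRangeWindow()
    cell = mask.grid.cell_size
    if window.radius < cell:
        raise ValueError("window radius must be at least one cell")
    kernel = _disk_kernel(window.radius, cell)
    counts = ndimage.convolve(mask.member.astype(float), kernel,
                              mode="constant", cval=0.0)
    return RasterLayer(name=name, grid=mask.grid,
                       values=np.rint(counts) * cell**2,
                       kind=LayerKind.CONTINUOUS)


def terrain_derivatives(dem: RasterLayer) -> dict[str, RasterLayer]:
    """Slope (degrees) and aspect (degrees clockwise from north) from a DEM.

    Uses the standard Horn 3x3 finite-difference stencil with edge rows and
    columns replicated. Flat cells have undefined aspect and are masked in
    the aspect layer.
    """
    if dem.grid.n_rows < 3 or dem.grid.n_cols < 3:
        raise ValueError("terrain derivatives need a grid of at least 3x3")
    z = np.pad(dem.values, 1, mode="edge")
    cell = dem.grid.cell_size
    # Horn weights; x increases with column, y decreases with row
    dzdx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * cell)
    dzdy = (
        (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
        - (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
    ) / (8 * cell)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    # aspect: downslope direction, clockwise from north, in [0, 360)
    aspect = np.mod(np.degrees(np.arctan2(-dzdx, -dzdy)), 360.0)
    flat = grad == 0
    aspect = np.where(flat, 0.0, aspect)
    slope_layer = RasterLayer(name="slope", grid=dem.grid, values=slope,
                              mask=dem.mask.copy(), kind=LayerKind.CONTINUOUS)
    aspect_layer = RasterLayer(name="aspect", grid=dem.grid, values=aspect,
                               mask=dem.mask | flat, kind=LayerKind.CIRCULAR)
    return {"slope": slope_layer, "aspect": aspect_layer}
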