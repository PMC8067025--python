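"""Aligned raster grids, point sets and study regions.

All coordinates are projected metres (UTM-like). A raster grid is defined by
its top-left corner, a square cell size and its shape; every layer taking part
in one analysis shares a single :class:`GridSpec`. Cells are half-open:
``[x0 + c*cell, x0 + (c+1)*cell)`` in x and ``(y0 - (r+1)*cell, y0 - r*cell]``
in y, so a point on a shared edge belongs to exactly one cell (the floor rule
below).

Rasters are stored on disk as single-band ESRI ASCII grids (``.asc``), a plain
text format; layer kind (continuous / categorical / circular degrees) travels
in the run configuration rather than in the file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
from scipy import ndimage
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry


class LayerKind(str, Enum):
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"
    CIRCULAR = "circular_degrees"


class PointLabel(str, Enum):
    PRESENCE = "presence"
    CARCASS = "carcass"
    BACKGROUND = "background"


@dataclass(frozen=True)
class GridSpec:
    """Square-celled raster grid in projected coordinates, top-left origin."""

    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x0, y0) of the top-left corner
    n_rows: int = 1
    n_cols: int = 1
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centres(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centres(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def centre_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shape (n_rows, n_cols)."""
        return np.meshgrid(self.x_centres(), self.y_centres())

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell containing each point, by the floor rule.

        row = floor((y0 - y)/cell), col = floor((x - x0)/cell).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class RasterLayer:
    """Named single-band raster aligned to a :class:`GridSpec`.

    ``mask`` is True where the cell holds no data; masked cells are excluded
    from every statistic. Circular layers store degrees in [0, 360).
    """

    name: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None
    kind: LayerKind = LayerKind.CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError(f"layer {self.name!r}: mask shape mismatch")
        self.kind = LayerKind(self.kind)
        if self.kind is LayerKind.CIRCULAR:
            valid = self.values[~self.mask]
            if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) >= 360):
                raise ValueError(f"circular layer {self.name!r} outside [0, 360)")

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy(self, **overrides) -> "RasterLayer":
        kw = dict(
            name=self.name,
            grid=self.grid,
            values=self.values.copy(),
            mask=self.mask.copy(),
            kind=self.kind,
        )
        kw.update(overrides)
        return RasterLayer(**kw)


class RasterStack:
    """Ordered collection of uniquely-named layers on one shared grid."""

    def __init__(self, layers: Iterable[RasterLayer]):
        self._layers: dict[str, RasterLayer] = {}
        self.grid: GridSpec | None = None
        for layer in layers:
            self.add(layer)
        if self.grid is None:
            raise ValueError("a RasterStack needs at least one layer")

    def add(self, layer: RasterLayer) -> None:
        if layer.name in self._layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if self.grid is None:
            self.grid = layer.grid
        elif layer.grid != self.grid:
            raise ValueError(f"layer {layer.name!r} is not on the shared grid")
        self._layers[layer.name] = layer

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers.values())

    def __len__(self) -> int:
        return len(self._layers)

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self._layers[n] for n in names])

    def combined_mask(self) -> np.ndarray:
        """True where any layer is nodata."""
        out = np.zeros(self.grid.shape, dtype=bool)
        for layer in self:
            out |= layer.mask
        return out

    def kinds(self) -> dict[str, LayerKind]:
        return {layer.name: layer.kind for layer in self}


@dataclass
class OccurrenceSet:
    """Labelled point records in projected coordinates."""

    xy: np.ndarray  # (n, 2)
    label: PointLabel
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, 2)
        if self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if not np.isfinite(self.xy).all():
            raise ValueError("coordinates must be finite")
        self.label = PointLabel(self.label)
        if not self.ids:
            self.ids = [f"{self.label.value}-{i}" for i in range(len(self.xy))]
        if len(self.ids) != len(self.xy):
            raise ValueError("ids and xy length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    def __len__(self) -> int:
        return len(self.xy)

    def subset(self, index: np.ndarray) -> "OccurrenceSet":
        index = np.asarray(index)
        return OccurrenceSet(
            xy=self.xy[index],
            label=self.label,
            ids=[self.ids[i] for i in np.flatnonzero(index)]
            if index.dtype == bool
            else [self.ids[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "x": self.xy[:, 0], "y": self.xy[:, 1],
             "label": self.label.value}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: PointLabel | str | None = None
                 ) -> "OccurrenceSet":
        df = pd.read_csv(path)
        for col in ("id", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"points CSV missing required column {col!r}")
        if label is None:
            if "label" not in df.columns:
                raise ValueError("points CSV has no 'label' column and none given")
            labels = set(df["label"])
            if len(labels) != 1:
                raise ValueError("points CSV mixes labels; pass label explicitly")
            label = labels.pop()
        return cls(
            xy=df[["x", "y"]].to_numpy(float),
            label=PointLabel(label),
            ids=[str(v) for v in df["id"]],
        )


@dataclass
class StudyRegion:
    """Named polygonal study region (shapely Polygon/MultiPolygon)."""

    polygon: BaseGeometry
    name: str = "region"

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.name!r}: polygon is not valid")
        if self.polygon.area <= 0:
            raise ValueError(f"region {self.name!r}: polygon has no area")

    @classmethod
    def from_geojson(cls, path: str | Path, name: str | None = None) -> "StudyRegion":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        elif obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]["geometry"]
        return cls(geojson_shape(obj), name=name or Path(path).stem)

    @classmethod
    def from_wkt(cls, text: str, name: str = "region") -> "StudyRegion":
        return cls(shapely.wkt.loads(text), name=name)

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon (boundary counts as inside)."""
        inside = shapely.contains_xy(self.polygon, x, y)
        on_edge = shapely.intersects_xy(self.polygon, x, y)
        return inside | on_edge


# ---------------------------------------------------------------------------
# ASCII-grid I/O

_NODATA = -9999.0


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid; nodata cells get the NODATA tag."""
    g = layer.grid
    yll = g.origin[1] - g.n_rows * g.cell_size
    vals = np.where(layer.mask, _NODATA, layer.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin[0]!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")


def read_ascii_grid(
    path: str | Path,
    name: str | None = None,
    kind: LayerKind | str = LayerKind.CONTINUOUS,
    crs_id: str = "local-metric",
) -> RasterLayer:
    """Read a single-band ESRI ASCII grid into a :class:`RasterLayer`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        values = np.loadtxt(fh, ndmin=2)
    try:
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + n_rows * cell
    except KeyError as exc:  # pragma: no cover - malformed file
        raise ValueError(f"{path}: missing ASCII-grid header field {exc}") from exc
    nodata = header.get("nodata_value", _NODATA)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != header "
                         f"({n_rows}, {n_cols})")
    grid = GridSpec(cell_size=cell, origin=(x0, y0), n_rows=n_rows,
                    n_cols=n_cols, crs_id=crs_id)
    mask = values == nodata
    return RasterLayer(name=name or path.stem, grid=grid, values=values,
                       mask=mask, kind=LayerKind(kind))


# ---------------------------------------------------------------------------
# Resampling and alignment

def resample_layer(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    """Resample one layer onto the target grid.

    Continuous layers use bilinear interpolation between source cell centres;
    categorical and circular layers take the value of the nearest source cell
    centre. Any target cell that draws on a nodata source cell, or whose
    centre falls outside the source extent, is masked.
    """
    src = layer.grid
    if src == target:
        return layer.copy(grid=target)
    tx, ty = target.centre_mesh()
    # fractional index of each target centre in source centre coordinates
    fi = (src.origin[1] - ty) / src.cell_size - 0.5
    fj = (tx - src.origin[0]) / src.cell_size - 0.5
    inside = (fi >= -0.5) & (fi <= src.n_rows - 0.5) & \
             (fj >= -0.5) & (fj <= src.n_cols - 0.5)
    if layer.kind is LayerKind.CONTINUOUS:
        order = 1
    else:
        order = 0
    coords = np.vstack([fi.ravel(), fj.ravel()])
    vals = ndimage.map_coordinates(layer.values, coords, order=order,
                                   mode="nearest").reshape(target.shape)
    touched = ndimage.map_coordinates(layer.mask.astype(float), coords,
                                      order=order, mode="nearest"
                                      ).reshape(target.shape)
    mask = (touched > 0) | ~inside
    return RasterLayer(name=layer.name, grid=target, values=vals, mask=mask,
                       kind=layer.kind)


def read_stack(
    paths: Sequence[str | Path],
    target: GridSpec,
    kinds: Mapping[str, LayerKind | str] | None = None,
) -> RasterStack:
    """Read raster files and align every layer to the target grid."""
    kinds = kinds or {}
    layers = []
    for path in paths:
        name = Path(path).stem
        try:
            layer = read_ascii_grid(path, name=name,
                                    kind=kinds.get(name, LayerKind.CONTINUOUS),
                                    crs_id=target.crs_id)
        except OSError as exc:
            raise OSError(f"cannot read raster layer {name!r}: {exc}") from exc
        layers.append(resample_layer(layer, target))
    return RasterStack(layers)


# ---------------------------------------------------------------------------
# Extraction and clipping

def extract_at_points(stack: RasterStack, pts: OccurrenceSet) -> pd.DataFrame:
    """Covariate table at point locations (one row per in-extent point).

    Each point takes the value of the cell that contains it under the floor
    rule. Rows touching any nodata cell are flagged in the boolean
    ``any_masked`` column. Points outside the grid extent are dropped; their
    count is warned about and stored in ``df.attrs['n_outside']``.
    """
    grid = stack.grid
    inside = grid.contains(pts.xy[:, 0], pts.xy[:, 1])
    n_outside = int((~inside).sum())
    if n_outside:
        warnings.warn(f"{n_outside} point(s) outside the grid extent were "
                      "dropped", stacklevel=2)
    kept = pts.subset(inside)
    row, col = grid.rowcol(kept.xy[:, 0], kept.xy[:, 1])
    data = {layer.name: layer.values[row, col] for layer in stack}
    any_masked = np.zeros(len(kept), dtype=bool)
    for layer in stack:
        any_masked |= layer.mask[row, col]
    df = pd.DataFrame(data, index=pd.Index(kept.ids, name="id"))
    df["any_masked"] = any_masked
    df.attrs["n_outside"] = n_outside
    return df


def clip_stack(stack: RasterStack, region: StudyRegion) -> RasterStack:
    """Mask every cell whose centre falls outside the region polygon."""
    gx, gy = stack.grid.centre_mesh()
    inside = region.contains_points(gx.ravel(), gy.ravel()).reshape(stack.grid.shape)
    if not inside.any():
        raise ValueError(f"region {region.name!r} does not intersect the grid")
    return RasterStack(
        [layer.copy(mask=layer.mask | ~inside) for layer in stack]
    )
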