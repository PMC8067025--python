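"""Raster grid, I/O, resampling, extraction and clipping behaviour."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from ensemblesdm.grids import (GridSpec, LayerKind, OccurrenceSet, PointLabel,
                               RasterLayer, RasterStack, StudyRegion,
                               clip_stack, extract_at_points,
                               read_ascii_grid, resample_layer,
                               write_ascii_grid)


class TestAsciiGridIO:
    def test_roundtrip_values_and_mask_bit_exact(self, grid5, rng, tmp_path):
        values = rng.normal(size=grid5.shape) * 1e6
        mask = rng.random(grid5.shape) < 0.3
        layer = RasterLayer("z", grid5, values, mask=mask)
        path = tmp_path / "z.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path, name="z")
        assert back.grid == grid5
        assert np.array_equal(back.mask, mask)
        assert np.array_equal(back.values[~mask], values[~mask])

    def test_missing_file_raises(self, grid5):
        from ensemblesdm.grids import read_stack

        with pytest.raises(OSError):
            read_stack(["/nonexistent/layer.asc"], grid5)


class TestResampling:
    def test_identity_on_own_grid(self, grid5, rng):
        layer = RasterLayer("a", grid5, rng.normal(size=grid5.shape))
        out = resample_layer(layer, grid5)
        assert np.array_equal(out.values, layer.values)

    def test_constant_layer_stays_constant(self, rng):
        src = GridSpec(cell_size=10.0, origin=(0.0, 120.0), n_rows=12,
                       n_cols=12)
        dst = GridSpec(cell_size=30.0, origin=(0.0, 120.0), n_rows=4,
                       n_cols=4)
        layer = RasterLayer("c", src, np.full(src.shape, 7.5))
        out = resample_layer(layer, dst)
        assert np.allclose(out.values[~out.mask], 7.5)

    def test_categorical_nearest_centre_matches_bruteforce(self, rng):
        src = GridSpec(cell_size=10.0, origin=(0.0, 120.0), n_rows=12,
                       n_cols=12)
        dst = GridSpec(cell_size=30.0, origin=(0.0, 120.0), n_rows=4,
                       n_cols=4)
        vals = rng.integers(0, 5, src.shape).astype(float)
        layer = RasterLayer("cat", src, vals, kind=LayerKind.CATEGORICAL)
        out = resample_layer(layer, dst)
        # oracle: nearest source-cell-centre value for every target centre
        sx, sy = src.centre_mesh()
        tx, ty = dst.centre_mesh()
        for i in range(dst.n_rows):
            for j in range(dst.n_cols):
                d2 = (sx - tx[i, j]) ** 2 + (sy - ty[i, j]) ** 2
                r, c = np.unravel_index(np.argmin(d2), src.shape)
                assert out.values[i, j] == vals[r, c]


class TestExtraction:
    def test_cell_centre_value(self, small_stack):
        g = small_stack.grid
        pts = OccurrenceSet(xy=[[g.x_centres()[2], g.y_centres()[1]]],
                            label=PointLabel.PRESENCE)
        df = extract_at_points(small_stack, pts)
        assert df.iloc[0]["a"] == small_stack["a"].values[1, 2]

    def test_shared_edge_floor_rule(self, small_stack):
        # a point exactly on the vertical edge between columns 1 and 2
        g = small_stack.grid
        x_edge = g.origin[0] + 2 * g.cell_size
        y = g.y_centres()[0]
        df = extract_at_points(
            small_stack, OccurrenceSet(xy=[[x_edge, y]], label="presence"))
        assert df.iloc[0]["a"] == small_stack["a"].values[0, 2]

    def test_random_points_match_bruteforce_containment(self, rng):
        grid = GridSpec(cell_size=30.0, origin=(10.0, 130.0), n_rows=4,
                        n_cols=4)
        vals = rng.normal(size=grid.shape)
        stack = RasterStack([RasterLayer("v", grid, vals)])
        xs = rng.uniform(10.0, 10.0 + 4 * 30.0 - 1e-9, 5)
        ys = rng.uniform(130.0 - 4 * 30.0 + 1e-9, 130.0, 5)
        df = extract_at_points(
            stack, OccurrenceSet(xy=np.column_stack([xs, ys]),
                                 label="presence"))
        for k, (x, y) in enumerate(zip(xs, ys)):
            hits = []
            for r in range(4):
                for c in range(4):
                    x0 = 10.0 + c * 30.0
                    y0 = 130.0 - r * 30.0
                    if x0 <= x < x0 + 30.0 and y0 - 30.0 < y <= y0:
                        hits.append((r, c))
            assert len(hits) == 1
            assert df.iloc[k]["v"] == vals[hits[0]]

    def test_outside_points_dropped_with_count(self, small_stack):
        pts = OccurrenceSet(xy=[[-999.0, 0.0], [15.0, 135.0]],
                            label="presence")
        with pytest.warns(UserWarning, match="outside"):
            df = extract_at_points(small_stack, pts)
        assert len(df) == 1
        assert df.attrs["n_outside"] == 1


class TestClipping:
    def test_full_cover_no_new_mask(self, small_stack):
        region = StudyRegion(box(-100, -100, 1000, 1000))
        out = clip_stack(small_stack, region)
        assert not out.combined_mask().any()

    def test_left_half_cell_count(self):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 300.0), n_rows=10,
                        n_cols=10)
        stack = RasterStack([RasterLayer("v", grid, np.zeros(grid.shape))])
        region = StudyRegion(box(0.0, 0.0, 150.0, 300.0))
        out = clip_stack(stack, region)
        assert (~out.combined_mask()).sum() == 50

    def test_random_polygon_matches_raycasting_oracle(self, rng):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 600.0), n_rows=20,
                        n_cols=20)
        stack = RasterStack([RasterLayer("v", grid, np.zeros(grid.shape))])
        pts = rng.uniform(0, 600, size=(6, 2))
        hull = Polygon(pts).convex_hull
        out = clip_stack(stack, StudyRegion(hull))
        ring = np.asarray(hull.exterior.coords)

        def ray_cast(x, y):
            inside = False
            for (x1, y1), (x2, y2) in zip(ring[:-1], ring[1:]):
                if (y1 > y) != (y2 > y):
                    xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xin:
                        inside = not inside
            return inside

        gx, gy = grid.centre_mesh()
        mask = out.combined_mask()
        mismatch = 0
        for i in range(20):
            for j in range(20):
                if mask[i, j] != (not ray_cast(gx[i, j], gy[i, j])):
                    mismatch += 1
        # boundary-touching centres may differ between the conventions
        assert mismatch <= 1

    def test_empty_intersection_raises(self, small_stack):
        with pytest.raises(ValueError, match="intersect"):
            clip_stack(small_stack,
                       StudyRegion(box(10_000, 10_000, 10_030, 10_030)))

    def test_extract_after_clip_flags_outside_cells(self, small_stack):
        region = StudyRegion(box(0.0, 60.0, 90.0, 150.0))  # upper-left 3x3
        clipped = clip_stack(small_stack, region)
        g = small_stack.grid
        inside_pt = [g.x_centres()[1], g.y_centres()[1]]
        outside_pt = [g.x_centres()[4], g.y_centres()[4]]
        df = extract_at_points(
            clipped, OccurrenceSet(xy=[inside_pt, outside_pt],
                                   label="presence"))
        assert not df.iloc[0]["any_masked"]
        assert df.iloc[1]["any_masked"]


class TestContainers:
    def test_duplicate_layer_names_rejected(self, grid5):
        layer = RasterLayer("a", grid5, np.zeros(grid5.shape))
        with pytest.raises(ValueError, match="duplicate"):
            RasterStack([layer, layer.copy()])

    def test_occurrence_csv_roundtrip(self, tmp_path):
        pts = OccurrenceSet(xy=[[1.5, 2.5], [3.5, 4.5]], label="carcass",
                            ids=["c1", "c2"])
        path = tmp_path / "pts.csv"
        pts.to_csv(path)
        back = OccurrenceSet.from_csv(path)
        assert back.label is PointLabel.CARCASS
        assert back.ids == ["c1", "c2"]
        assert np.array_equal(back.xy, pts.xy)

    def test_points_csv_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": [1], "x": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="'y'"):
            OccurrenceSet.from_csv(path, label="presence")
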