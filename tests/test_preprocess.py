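"""Spatial thinning, background sampling and VIF screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from ensemblesdm.grids import GridSpec, OccurrenceSet, StudyRegion
from ensemblesdm.preprocess import (BackgroundConfig, ThinningConfig,
                                    VifConfig, compute_vif,
                                    sample_background, spatial_thin,
                                    vif_stepwise)


class TestSpatialThin:
    def test_already_sparse_unchanged(self):
        xy = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        pts = OccurrenceSet(xy=xy, label="presence")
        out = spatial_thin(pts, ThinningConfig(seed=1))
        assert len(out) == 3

    def test_close_pair_keeps_one(self):
        pts = OccurrenceSet(xy=[[0.0, 0.0], [10.0, 0.0]], label="presence")
        out = spatial_thin(pts, ThinningConfig(seed=1))
        assert len(out) == 1

    def test_matches_exhaustive_max_independent_set(self):
        rng = np.random.default_rng(3)
        xy = np.vstack([rng.normal(c, 300.0, size=(4, 2))
                        for c in ((0, 0), (1500, 0), (0, 1500))])
        pts = OccurrenceSet(xy=xy, label="presence")
        cfg = ThinningConfig(min_distance=682.0, n_repeats=100, seed=9)
        out = spatial_thin(pts, cfg)
        best = 0
        for r in range(1, 13):
            for combo in itertools.combinations(range(12), r):
                sub = xy[list(combo)]
                d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
                if (d[np.triu_indices(r, 1)] >= 682.0).all():
                    best = max(best, r)
        assert len(out) == best

    def test_output_subset_and_min_distance(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 2000, size=(40, 2))
        pts = OccurrenceSet(xy=xy, label="presence")
        out = spatial_thin(pts, ThinningConfig(seed=2))
        assert 1 <= len(out) <= 40
        assert set(out.ids) <= set(pts.ids)
        d = np.linalg.norm(out.xy[:, None] - out.xy[None, :], axis=2)
        iu = np.triu_indices(len(out), 1)
        assert (d[iu] >= 682.0).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        pts = OccurrenceSet(xy=rng.uniform(0, 1500, (25, 2)),
                            label="presence")
        a = spatial_thin(pts, ThinningConfig(seed=4))
        b = spatial_thin(pts, ThinningConfig(seed=4))
        assert a.ids == b.ids


class TestBackground:
    def test_single_cell_polygon(self):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 150.0), n_rows=5,
                        n_cols=5)
        region = StudyRegion(box(30.0, 90.0, 60.0, 120.0))  # one cell
        out = sample_background(BackgroundConfig(n_points=1, region=region,
                                                 seed=0), grid)
        assert np.allclose(out.xy, [[45.0, 105.0]])

    def test_exhaustion_samples_every_cell(self):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 90.0), n_rows=3,
                        n_cols=3)
        out = sample_background(BackgroundConfig(n_points=9, seed=1), grid)
        assert len({tuple(p) for p in out.xy}) == 9

    def test_too_few_candidates_error(self):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 60.0), n_rows=2,
                        n_cols=2)
        with pytest.raises(ValueError, match="candidate"):
            sample_background(BackgroundConfig(n_points=5, seed=0), grid)

    def test_seed_determinism_and_variation(self):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 300.0), n_rows=10,
                        n_cols=10)
        a = sample_background(BackgroundConfig(n_points=10, seed=3), grid)
        b = sample_background(BackgroundConfig(n_points=10, seed=3), grid)
        c = sample_background(BackgroundConfig(n_points=10, seed=4), grid)
        assert np.array_equal(a.xy, b.xy)
        assert not np.array_equal(a.xy, c.xy)

    def test_respects_region_and_mask(self):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 300.0), n_rows=10,
                        n_cols=10)
        region = StudyRegion(box(0.0, 150.0, 300.0, 300.0))  # upper half
        mask = np.zeros(grid.shape, bool)
        mask[:, :5] = True  # left half nodata
        out = sample_background(BackgroundConfig(n_points=20, region=region,
                                                 seed=2), grid, mask)
        assert (out.xy[:, 1] > 150.0).all()
        assert (out.xy[:, 0] > 150.0).all()


class TestVif:
    def test_orthogonal_columns_unit_vif(self, rng):
        n = 200
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        vifs = compute_vif(pd.DataFrame({"a": a, "b": b}))
        assert vifs["a"] == pytest.approx(1.0, abs=1e-6)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-6)

    def test_exact_sum_column_infinite(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        vifs = compute_vif(pd.DataFrame({"a": a, "b": b, "c": a + b}))
        assert vifs["c"] == np.inf

    def test_matches_statsmodels_oracle(self, rng):
        cov = np.array([[1.0, 0.7, 0.2, 0.0], [0.7, 1.0, 0.3, 0.1],
                        [0.2, 0.3, 1.0, 0.5], [0.0, 0.1, 0.5, 1.0]])
        X = rng.multivariate_normal(np.zeros(4), cov, size=500)
        df = pd.DataFrame(X, columns=list("abcd"))
        vifs = compute_vif(df)
        from statsmodels.stats.outliers_influence import \
            variance_inflation_factor

        arr = np.column_stack([np.ones(500), X])
        for j, name in enumerate(df.columns):
            assert vifs[name] == pytest.approx(
                variance_inflation_factor(arr, j + 1), rel=1e-8)

    def test_stepwise_all_below_cutoff_untouched(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        retained, excluded = vif_stepwise(X, VifConfig())
        assert excluded == []
        assert retained == list("abcd")

    def test_duplicated_column_one_copy_removed(self, rng):
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "dup": a.copy(),
                          "b": rng.normal(size=100)})
        retained, excluded = vif_stepwise(X)
        assert len(excluded) == 1
        assert excluded[0] in {"a", "dup"}
        assert ({"a", "dup"} & set(retained)) != set()

    def test_stepwise_matches_manual_iteration(self, rng):
        latent = rng.normal(size=300)
        X = pd.DataFrame({
            "u": latent + rng.normal(0, 0.3, 300),
            "v": latent + rng.normal(0, 0.3, 300),
            "w": latent + rng.normal(0, 0.3, 300),
            "z": rng.normal(size=300),
        })
        retained, excluded = vif_stepwise(X, VifConfig())
        cols = list(X.columns)
        expected = []
        while len(cols) >= 2:
            vifs = compute_vif(X[cols])
            worst = max(vifs.values())
            if worst < 5.0:
                break
            victim = next(c for c in cols if vifs[c] == worst)
            cols.remove(victim)
            expected.append(victim)
        assert excluded == expected
        assert retained == cols
        if len(retained) >= 2:
            assert max(compute_vif(X[retained]).values()) < 5.0

    def test_rejects_missing_values(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0, 3.0],
                          "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="missing"):
            compute_vif(X.iloc[:3])
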