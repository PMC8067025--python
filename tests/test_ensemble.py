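"""Importance, response curves, forward selection and the median committee."""

import numpy as np
import pandas as pd
import pytest

from ensemblesdm.algorithms import TrainingSet, fit
from ensemblesdm.ensemble import (SelectionConfig, _classify_shape, binarize,
                                  ensemble_predict, ensemble_predict_table,
                                  evaluate_ensemble, forward_select,
                                  loo_importance, relative_importance,
                                  response_curve)
from ensemblesdm.evaluation import CvConfig
from ensemblesdm.grids import GridSpec, LayerKind, RasterLayer, RasterStack


def _make_train(betas, n=240, seed=0, extra_noise=0):
    rng = np.random.default_rng(seed)
    p = len(betas) + extra_noise
    X = rng.normal(size=(n, p))
    logit = X[:, :len(betas)] @ np.asarray(betas)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    y[:2] = [0, 1]
    cols = [f"v{j}" for j in range(p)]
    return TrainingSet(pd.DataFrame(X, columns=cols), y)


class TestRelativeImportance:
    def test_simple_division(self):
        out = relative_importance({"a": 0.3, "b": 0.1, "c": 0.1})
        assert out == pytest.approx({"a": 0.6, "b": 0.2, "c": 0.2})

    def test_single_variable_is_one(self):
        assert relative_importance({"only": 0.42}) == {"only": 1.0}

    def test_sums_to_one(self, rng):
        raw = {f"v{i}": float(v) for i, v in enumerate(rng.random(7))}
        assert sum(relative_importance(raw).values()) == pytest.approx(
            1.0, abs=1e-12)

    def test_renormalization_preserves_ratios(self, rng):
        raw = {"a": 0.5, "b": 0.3, "c": 0.2}
        full = relative_importance(raw)
        dropped = relative_importance({k: raw[k] for k in ("a", "b")})
        assert full["a"] / full["b"] == pytest.approx(
            dropped["a"] / dropped["b"])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_importance({"a": 0.0, "b": 0.0})


class TestLooImportance:
    def test_uninformative_exclusion_near_zero(self):
        train = _make_train([2.5], extra_noise=1, n=300)
        cv = CvConfig(k=4, n_repeats=1, seed=0)
        imp = loo_importance("GLM", train, train.variables, cv)
        # dropping the noise column leaves AUC high -> small importance
        assert imp["v1"] < imp["v0"]
        assert imp["v1"] < 0.25

    def test_single_variable_convention(self):
        train = _make_train([2.0])
        cv = CvConfig(k=4, n_repeats=1, seed=0)
        imp = loo_importance("BIOCLIM", train, ["v0"], cv)
        assert imp["v0"] == 0.5

    def test_matches_from_scratch_refit_oracle(self):
        from ensemblesdm.evaluation import cross_validate

        train = _make_train([1.5, 1.0], extra_noise=1, n=200, seed=4)
        cv = CvConfig(k=4, n_repeats=1, seed=9)
        imp = loo_importance("BIOCLIM", train, train.variables, cv)
        for v in train.variables:
            rest = [w for w in train.variables if w != v]
            folds = cross_validate("BIOCLIM", train.subset_variables(rest),
                                   cv)
            assert imp[v] == pytest.approx(
                max(0.0, 1.0 - folds["auc"].mean()))


class TestResponseCurves:
    def test_shape_classifier_on_analytic_profiles(self):
        z = np.linspace(0, 1, 100)
        assert _classify_shape(1 / (1 + np.exp(-8 * (z - 0.5))))[0] \
            == "increasing"
        assert _classify_shape(1 - z * 0.8)[0] == "decreasing"
        assert _classify_shape(0.8 * np.exp(-((z - 0.5) / 0.2) ** 2))[0] \
            == "unimodal"
        assert _classify_shape(np.full(100, 0.4))[0] == "other"  # flat
        valley = 0.8 - 0.7 * np.exp(-((z - 0.5) / 0.2) ** 2)
        assert _classify_shape(valley)[0] == "other"

    def test_model_ignoring_variable_flat_flagged(self):
        train = _make_train([2.0], extra_noise=1, n=300)
        inner = fit("GLM", train.subset_variables(["v0"]))

        class IgnoresV1:
            variables = ["v0", "v1"]

            def predict(self, X):
                return inner.predict(X[["v0"]])

        rc = response_curve(IgnoresV1(), train, "v1")
        assert rc.shape == "other"
        assert rc.flat

    def test_logistic_generator_increasing(self):
        train = _make_train([2.5], n=400, seed=2)
        model = fit("GAM", train)
        assert response_curve(model, train, "v0").shape == "increasing"

    def test_quadratic_generator_unimodal(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 400)
        logit = 2.0 - 3.0 * x**2
        y = (rng.random(400) < 1 / (1 + np.exp(-logit))).astype(int)
        y[:2] = [0, 1]
        train = TrainingSet(pd.DataFrame({"v0": x}), y)
        model = fit("GLM", train)
        assert response_curve(model, train, "v0").shape == "unimodal"

    def test_constant_variable_rejected(self):
        train = _make_train([2.0], n=50)
        train.X["flat"] = 1.0
        model = fit("RF", train.subset_variables(["v0"]), seed=0)
        with pytest.raises(ValueError, match="constant"):
            response_curve(model, train, "flat")


class TestMedianEnsemble:
    def _stack_of(self, values_list):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 30.0), n_rows=1,
                        n_cols=1)
        return grid

    def test_odd_membership_median(self):
        class Fixed:
            def __init__(self, v):
                self.v = v
                self.variables = ["x"]

            def predict(self, X):
                return np.full(len(X), self.v)

        X = pd.DataFrame({"x": [0.0]})
        assert ensemble_predict_table([Fixed(0.2), Fixed(0.5), Fixed(0.9)],
                                      X)[0] == 0.5
        assert ensemble_predict_table([Fixed(0.2), Fixed(0.4)], X)[0] \
            == pytest.approx(0.3)
        assert ensemble_predict_table([Fixed(0.7)], X)[0] == 0.7

    def test_bounded_by_member_envelope(self, toy_training):
        members = [fit(a, toy_training, seed=0)
                   for a in ("GLM", "RF", "BIOCLIM")]
        preds = np.vstack([m.predict(toy_training.X) for m in members])
        med = ensemble_predict_table(members, toy_training.X)
        assert (med >= preds.min(axis=0) - 1e-12).all()
        assert (med <= preds.max(axis=0) + 1e-12).all()

    def test_stack_prediction_respects_mask(self, toy_training):
        grid = GridSpec(cell_size=30.0, origin=(0.0, 90.0), n_rows=3,
                        n_cols=3)
        rng = np.random.default_rng(0)
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        stack = RasterStack([
            RasterLayer("x1", grid, rng.normal(size=(3, 3)), mask=mask),
            RasterLayer("x2", grid, rng.normal(size=(3, 3))),
        ])
        members = [fit("GLM", toy_training)]
        out = ensemble_predict(members, stack, ["x1", "x2"])
        assert out.mask[0, 0]
        assert not out.mask[1:].any()


class TestEvaluateEnsemble:
    def test_identical_members_match_single(self):
        train = _make_train([2.0], n=160, seed=6)
        cv = CvConfig(k=4, n_repeats=1, seed=2)
        single = evaluate_ensemble(["GLM"], train, cv)
        double = evaluate_ensemble(["GLM", "GLM"], train, cv)
        assert single["auc"] == pytest.approx(double["auc"])
        assert single["tss"] == pytest.approx(double["tss"])

    def test_median_of_perfect_and_antiperfect_toy(self):
        # on a 6-point set: two perfect scorers and one anti-perfect scorer;
        # the 3-member median equals the perfect ranking -> AUC 1
        scores_perfect = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        anti = 1 - scores_perfect
        labels = np.array([1, 1, 1, 0, 0, 0])
        med = np.median(np.vstack([scores_perfect, scores_perfect, anti]),
                        axis=0)
        from ensemblesdm.evaluation import auc

        assert auc(med, labels) == 1.0

    def test_ensemble_not_much_worse_than_members(self):
        train = _make_train([2.0, 1.5], n=240, seed=8)
        cv = CvConfig(k=4, n_repeats=1, seed=3)
        from ensemblesdm.evaluation import cross_validate

        member_aucs = [cross_validate(a, train, cv)["auc"].mean()
                       for a in ("GLM", "GAM")]
        ens = evaluate_ensemble(["GLM", "GAM"], train, cv)
        assert ens["auc"] >= min(member_aucs) - 0.05


class TestBinarize:
    def _layer(self, values):
        values = np.asarray(values, float)
        grid = GridSpec(cell_size=30.0, origin=(0.0, values.shape[0] * 30.0),
                        n_rows=values.shape[0], n_cols=values.shape[1])
        return RasterLayer("s", grid, values)

    def test_threshold_zero_all_one(self):
        out = binarize(self._layer([[0.2, 0.8]]), 0.0)
        assert (out.values == 1).all()

    def test_threshold_above_max_all_zero(self):
        out = binarize(self._layer([[0.2, 0.8]]), 0.9)
        assert (out.values == 0).all()

    def test_three_by_three_pattern(self):
        vals = [[0.1, 0.5, 0.9], [0.49, 0.51, 0.2], [1.0, 0.0, 0.5]]
        out = binarize(self._layer(vals), 0.5)
        assert np.array_equal(
            out.values, [[0, 1, 1], [0, 1, 0], [1, 0, 1]])


class TestForwardSelect:
    def test_recovers_informative_rejects_noise(self):
        train = _make_train([2.5], extra_noise=3, n=300, seed=1)
        cv = CvConfig(k=4, n_repeats=1, seed=1)
        selected, table, audit = forward_select(
            train.variables, train, cv, SelectionConfig(seed=0),
            algorithms=("BIOCLIM", "DOMAIN", "GLM", "GAM", "MAXENT"))
        assert "v0" in selected
        assert len(set(selected) - {"v0"}) <= 1

    def test_all_noise_flagged_empty(self):
        train = _make_train([0.0], extra_noise=2, n=200, seed=5)
        cv = CvConfig(k=4, n_repeats=1, seed=1)
        selected, table, audit = forward_select(
            train.variables, train, cv, SelectionConfig(seed=0),
            algorithms=("BIOCLIM", "GLM", "GAM"))
        assert selected == []
        assert audit[-1]["action"] == "flag"

    def test_same_seed_identical_audit(self):
        train = _make_train([2.0], extra_noise=1, n=200, seed=2)
        cv = CvConfig(k=4, n_repeats=1, seed=7)
        cfg = SelectionConfig(seed=3)
        algos = ("BIOCLIM", "GLM", "GAM")
        _, _, a = forward_select(train.variables, train, cv, cfg,
                                 algorithms=algos)
        _, _, b = forward_select(train.variables, train, cv, cfg,
                                 algorithms=algos)
        assert a == b
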