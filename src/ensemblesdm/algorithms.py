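"""The eight presence-background modelling algorithms behind one contract.

Envelope / distance approaches (BIOCLIM, Domain) are defined here in full:

* BIOCLIM scores a site per variable by the tie-adjusted percentile of its
  value within the presence records, folded into a tail score
  ``2 * min(p, 1 - p)``; the site score is the minimum over variables, and
  values strictly outside the presence range score 0.
* Domain scores a site by ``max(0, 1 - d)`` where ``d`` is the Gower distance
  to the most similar presence record (mean over variables of the absolute
  difference divided by the variable's presence range).

The regression and machine-learning algorithms (GLM, GAM, CART, RF, BRT,
Maxent-style penalized logistic) delegate to scikit-learn estimators under
fixed, checked-in default hyperparameters. All predictions lie in [0, 1] and
stochastic learners are bit-reproducible for a fixed seed.

Circular variables (aspect, degrees) enter the discriminative algorithms as a
sin/cos pair; the envelope algorithms receive raw degrees (a documented caveat
of the classic formulations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import SplineTransformer
from sklearn.tree import DecisionTreeClassifier

from .grids import LayerKind

ALGORITHM_NAMES = (
    "BIOCLIM", "DOMAIN", "GLM", "GAM", "CART", "RF", "BRT", "MAXENT",
)

#: Checked-in default hyperparameters for every algorithm.
DEFAULT_HYPER: dict[str, dict] = {
    "GLM": {},                                   # linear + quadratic terms
    "GAM": {"n_knots": 4, "degree": 3, "C": 1.0},
    "CART": {"cv_folds": 5, "max_alphas": 20},
    "RF": {"n_trees": 500},
    "BRT": {"learning_rate": 0.01, "tree_complexity": 2, "bag_fraction": 0.75,
            "max_trees": 500, "n_iter_no_change": 10, "tol": 1e-7},
    "MAXENT": {"n_hinge": 5, "C": 1.0},
    "BIOCLIM": {},
    "DOMAIN": {},
}


class DegenerateInputError(ValueError):
    """Raised when an algorithm cannot be fit on the given training data."""


@dataclass
class TrainingSet:
    """Covariate table plus binary labels (1 presence/carcass, 0 background)."""

    X: pd.DataFrame
    y: np.ndarray
    variable_kinds: dict[str, LayerKind] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        for name in self.X.columns:
            self.variable_kinds.setdefault(name, LayerKind.CONTINUOUS)

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)

    def presences(self) -> pd.DataFrame:
        return self.X[self.y == 1]

    def subset_variables(self, names: Sequence[str]) -> "TrainingSet":
        return TrainingSet(self.X[list(names)].copy(), self.y.copy(),
                           {n: self.variable_kinds[n] for n in names})

    def subset_rows(self, index: np.ndarray) -> "TrainingSet":
        return TrainingSet(self.X.iloc[index].copy(), self.y[index],
                           dict(self.variable_kinds))


# ---------------------------------------------------------------------------
# Design-matrix helpers for the discriminative algorithms

def _circular_expand(X: pd.DataFrame, kinds: Mapping[str, LayerKind]
                     ) -> tuple[np.ndarray, list[str]]:
    """Replace circular columns by (sin, cos) pairs; track source variables."""
    cols, sources = [], []
    for name in X.columns:
        v = X[name].to_numpy(float)
        if kinds.get(name) is LayerKind.CIRCULAR:
            theta = np.radians(v)
            cols += [np.sin(theta), np.cos(theta)]
            sources += [name, name]
        else:
            cols.append(v)
            sources.append(name)
    return np.column_stack(cols), sources


@dataclass
class _FeatureMap:
    """Standardized derived design matrix with a column -> variable map."""

    means: np.ndarray
    sds: np.ndarray
    sources: list[str]
    expand: str  # 'linear', 'quadratic', 'spline', 'hinge'
    hinge_knots: list[np.ndarray] | None = None
    splines: list[SplineTransformer] | None = None

    @classmethod
    def build(cls, X: pd.DataFrame, kinds: Mapping[str, LayerKind],
              expand: str, hyper: Mapping | None = None) -> "_FeatureMap":
        base, sources = _circular_expand(X, kinds)
        means = base.mean(axis=0)
        sds = base.std(axis=0)
        if expand == "quadratic" and np.any(sds == 0):
            flat = sorted({s for s, sd in zip(sources, sds) if sd == 0})
            raise DegenerateInputError(
                f"constant column(s) {flat} cannot take a quadratic term"
            )
        sds = np.where(sds == 0, 1.0, sds)
        fm = cls(means=means, sds=sds, sources=sources, expand=expand)
        hyper = hyper or {}
        z = (base - means) / sds
        if expand == "hinge":
            n_hinge = int(hyper.get("n_hinge", 5))
            qs = np.linspace(0.05, 0.95, n_hinge)
            fm.hinge_knots = [np.quantile(z[:, j], qs) for j in range(z.shape[1])]
        elif expand == "spline":
            fm.splines = []
            for j in range(z.shape[1]):
                st = SplineTransformer(
                    n_knots=int(hyper.get("n_knots", 4)),
                    degree=int(hyper.get("degree", 3)),
                    include_bias=False,
                )
                st.fit(z[:, [j]])
                fm.splines.append(st)
        return fm

    def transform(self, X: pd.DataFrame, kinds: Mapping[str, LayerKind]
                  ) -> tuple[np.ndarray, list[str]]:
        base, sources = _circular_expand(X, kinds)
        z = (base - self.means) / self.sds
        if self.expand == "linear":
            return z, list(sources)
        if self.expand == "quadratic":
            return (np.column_stack([z, z**2]), list(sources) * 2)
        cols, out_sources = [], []
        if self.expand == "spline":
            for j, st in enumerate(self.splines):
                basis = st.transform(z[:, [j]])
                cols.append(basis)
                out_sources += [sources[j]] * basis.shape[1]
            return np.hstack(cols), out_sources
        # hinge: linear + quadratic + right hinges at training quantiles
        cols = [z, z**2]
        out_sources = list(sources) * 2
        for j, knots in enumerate(self.hinge_knots):
            hz = np.maximum(0.0, z[:, [j]] - knots[None, :])
            cols.append(hz)
            out_sources += [sources[j]] * len(knots)
        return np.hstack(cols), out_sources


# ---------------------------------------------------------------------------
# Model classes

class SdmModel:
    """Fitted algorithm instance exposing a uniform suitability contract."""

    algorithm: str = ""
    needs_background = True

    def __init__(self, hyper: Mapping | None = None, seed: int = 0):
        self.hyper = {**DEFAULT_HYPER.get(self.algorithm, {}), **(hyper or {})}
        self.seed = int(seed)
        self.variables: list[str] = []
        self.variable_kinds: dict[str, LayerKind] = {}

    # -- contract ----------------------------------------------------------
    def fit(self, train: TrainingSet) -> "SdmModel":
        if train.X.shape[1] < 1:
            raise DegenerateInputError("no covariates to fit on")
        if self.needs_background and (train.y.min() == train.y.max()):
            raise DegenerateInputError(
                f"{self.algorithm} needs both presence and background rows"
            )
        if train.y.sum() < 1:
            raise DegenerateInputError("no presence rows")
        self.variables = train.variables
        self.variable_kinds = dict(train.variable_kinds)
        self._fit(train)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Suitability in [0, 1] for every row of X (columns by name)."""
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise KeyError(f"{self.algorithm}: missing column(s) {missing}")
        X = X[self.variables]
        if len(X) == 0:
            return np.zeros(0)
        out = np.clip(self._predict(X), 0.0, 1.0)
        return np.asarray(out, dtype=float)

    def _fit(self, train: TrainingSet) -> None:  # pragma: no cover
        raise NotImplementedError

    def _predict(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # -- importance --------------------------------------------------------
    def native_importance(self) -> dict[str, float] | None:
        """Per-variable importance from the fitting routine, or None."""
        return None

    @staticmethod
    def _aggregate(sources: Sequence[str], weights: np.ndarray
                   ) -> dict[str, float]:
        agg: dict[str, float] = {}
        for s, w in zip(sources, weights):
            agg[s] = agg.get(s, 0.0) + float(abs(w))
        return agg


class BioclimModel(SdmModel):
    """Classic percentile-envelope algorithm (presence-only)."""

    algorithm = "BIOCLIM"
    needs_background = False

    def _fit(self, train: TrainingSet) -> None:
        P = train.presences().to_numpy(float)
        if len(P) < 1:
            raise DegenerateInputError("BIOCLIM needs at least one presence")
        self._sorted = [np.sort(P[:, j]) for j in range(P.shape[1])]

    def _predict(self, X: pd.DataFrame) -> np.ndarray:
        arr = X.to_numpy(float)
        score = np.ones(len(arr))
        for j, sv in enumerate(self._sorted):
            x = arr[:, j]
            n = len(sv)
            lo = np.searchsorted(sv, x, side="left")
            hi = np.searchsorted(sv, x, side="right")
            p = (lo + 0.5 * (hi - lo)) / n
            s = 2.0 * np.minimum(p, 1.0 - p)
            s = np.where((x < sv[0]) | (x > sv[-1]), 0.0, s)
            score = np.minimum(score, s)
        return score


class DomainModel(SdmModel):
    """Gower-distance similarity to the nearest presence (presence-only)."""

    algorithm = "DOMAIN"
    needs_background = False

    def _fit(self, train: TrainingSet) -> None:
        P = train.presences().to_numpy(float)
        if len(P) < 2:
            raise DegenerateInputError("DOMAIN needs at least two presences")
        rng = P.max(axis=0) - P.min(axis=0)
        usable = rng > 0
        if not usable.all():
            dropped = [v for v, u in zip(self.variables, usable) if not u]
            warnings.warn(f"DOMAIN: dropping zero-range variable(s) {dropped}",
                          stacklevel=2)
        if not usable.any():
            raise DegenerateInputError("DOMAIN: all presence ranges are zero")
        self._P = P[:, usable]
        self._range = rng[usable]
        self._usable = usable

    def _predict(self, X: pd.DataFrame) -> np.ndarray:
        arr = X.to_numpy(float)[:, self._usable]
        p = arr.shape[1]
        # pairwise mean absolute scaled difference, min over presences
        from scipy.spatial.distance import cdist

        d = cdist(arr / self._range, self._P / self._range,
                  metric="cityblock") / p
        return np.maximum(0.0, 1.0 - d.min(axis=1))


class _SklearnModel(SdmModel):
    expand = "linear"

    def _make_estimator(self):  # pragma: no cover
        raise NotImplementedError

    def _fit(self, train: TrainingSet) -> None:
        self._fm = _FeatureMap.build(train.X, train.variable_kinds,
                                     self.expand, self.hyper)
        Z, self._sources = self._fm.transform(train.X, train.variable_kinds)
        self._est = self._make_estimator()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._est.fit(Z, train.y)

    def _predict(self, X: pd.DataFrame) -> np.ndarray:
        Z, _ = self._fm.transform(X, self.variable_kinds)
        return self._est.predict_proba(Z)[:, 1]


class GlmModel(_SklearnModel):
    """Unpenalized logistic regression with linear + quadratic terms."""

    algorithm = "GLM"
    expand = "quadratic"

    def _make_estimator(self):
        return LogisticRegression(penalty=None, max_iter=1000)

    def native_importance(self) -> dict[str, float]:
        # caret-style |coefficient z| summed over each variable's terms
        return self._aggregate(self._sources, self._est.coef_[0])


class GamModel(_SklearnModel):
    """Additive spline-logistic model (penalized smooth per variable)."""

    algorithm = "GAM"
    expand = "spline"

    def _make_estimator(self):
        return LogisticRegression(penalty="l2", C=float(self.hyper["C"]),
                                  max_iter=1000)

    def native_importance(self) -> dict[str, float]:
        return self._aggregate(self._sources, self._est.coef_[0])


class CartModel(_SklearnModel):
    """Classification tree with cost-complexity pruning by internal CV."""

    algorithm = "CART"
    expand = "linear"

    def _fit(self, train: TrainingSet) -> None:
        self._fm = _FeatureMap.build(train.X, train.variable_kinds,
                                     self.expand, self.hyper)
        Z, self._sources = self._fm.transform(train.X, train.variable_kinds)
        path = DecisionTreeClassifier(random_state=self.seed
                                      ).cost_complexity_pruning_path(Z, train.y)
        alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
        max_alphas = int(self.hyper["max_alphas"])
        if len(alphas) > max_alphas:
            alphas = alphas[np.linspace(0, len(alphas) - 1, max_alphas,
                                        dtype=int)]
        best_alpha, best_score = 0.0, -np.inf
        k = min(int(self.hyper["cv_folds"]), int(train.y.sum()),
                int((1 - train.y).sum()))
        if k >= 2 and len(alphas) > 1:
            cv = StratifiedKFold(n_splits=k, shuffle=True,
                                 random_state=self.seed)
            for a in alphas:
                est = DecisionTreeClassifier(ccp_alpha=a,
                                             random_state=self.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    score = cross_val_score(est, Z, train.y, cv=cv,
                                            scoring="roc_auc").mean()
                if score > best_score:
                    best_alpha, best_score = a, score
        self._est = DecisionTreeClassifier(ccp_alpha=best_alpha,
                                           random_state=self.seed)
        self._est.fit(Z, train.y)

    def native_importance(self) -> dict[str, float]:
        return self._aggregate(self._sources, self._est.feature_importances_)


class RfModel(_SklearnModel):
    """Random forest; probability = presence vote fraction."""

    algorithm = "RF"
    expand = "linear"

    def _make_estimator(self):
        return RandomForestClassifier(n_estimators=int(self.hyper["n_trees"]),
                                      random_state=self.seed, n_jobs=1)

    def native_importance(self) -> dict[str, float]:
        return self._aggregate(self._sources, self._est.feature_importances_)


class BrtModel(_SklearnModel):
    """Stagewise boosted trees on bernoulli deviance with internal holdout."""

    algorithm = "BRT"
    expand = "linear"

    def _make_estimator(self):
        return GradientBoostingClassifier(
            learning_rate=float(self.hyper["learning_rate"]),
            max_depth=int(self.hyper["tree_complexity"]),
            subsample=float(self.hyper["bag_fraction"]),
            n_estimators=int(self.hyper["max_trees"]),
            n_iter_no_change=int(self.hyper["n_iter_no_change"]),
            tol=float(self.hyper["tol"]),
            validation_fraction=0.2,
            random_state=self.seed,
        )

    def native_importance(self) -> dict[str, float]:
        return self._aggregate(self._sources, self._est.feature_importances_)


class MaxentModel(_SklearnModel):
    """Maxent-style penalized logistic contrast on linear+quadratic+hinge
    features (lasso penalty, hinge knots at training quantiles)."""

    algorithm = "MAXENT"
    expand = "hinge"

    def _make_estimator(self):
        return LogisticRegression(penalty="l1", C=float(self.hyper["C"]),
                                  solver="liblinear", random_state=self.seed)


_MODEL_CLASSES: dict[str, type[SdmModel]] = {
    cls.algorithm: cls
    for cls in (BioclimModel, DomainModel, GlmModel, GamModel, CartModel,
                RfModel, BrtModel, MaxentModel)
}


def fit(algorithm: str, train: TrainingSet, hyper: Mapping | None = None,
        seed: int = 0) -> SdmModel:
    """Fit one named algorithm on a training set."""
    algorithm = algorithm.upper()
    if algorithm not in _MODEL_CLASSES:
        raise KeyError(f"unknown algorithm {algorithm!r}; "
                       f"choose from {ALGORITHM_NAMES}")
    return _MODEL_CLASSES[algorithm](hyper=hyper, seed=seed).fit(train)


def predict_bioclim(model: BioclimModel, x: Sequence[float]) -> float:
    """Scalar BIOCLIM suitability for one covariate vector."""
    return float(model.predict(pd.DataFrame([x], columns=model.variables))[0])


def predict_domain(model: DomainModel, x: Sequence[float]) -> float:
    """Scalar Domain (Gower) suitability for one covariate vector."""
    return float(model.predict(pd.DataFrame([x], columns=model.variables))[0])
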