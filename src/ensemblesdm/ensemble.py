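"""Variable selection, importance, response curves and the median ensemble.

The model object (:class:`EnsembleSDM`) holds a presence-background training
table plus configuration; :meth:`EnsembleSDM.fit` runs the full procedure —
stepwise VIF screening, forward variable selection on average relative
importance with response-shape screening, repeated-CV evaluation of the eight
algorithms, the goodness-of-fit gate, and the cellwise-median committee of
the admitted members — and returns an :class:`EnsembleSDMResults` carrying
the selected variables, the importance table, CV metrics, the max-TSS
binarization threshold and prediction methods.

Variable importance follows the two-track convention: algorithms without a
native importance (BIOCLIM, Domain, Maxent) use leave-one-variable-out CV
(importance = 1 - AUC of the model refit without the variable); the others
use their fitting routine's native importance. Each algorithm's raw
importances are min-max rescaled and normalized to sum to one before
averaging, so both tracks are commensurable; relative importance is the raw
importance divided by the total.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import algorithms as alg
from . import evaluation as ev
from .algorithms import ALGORITHM_NAMES, TrainingSet
from .evaluation import CvConfig, CvReport, GateConfig
from .grids import LayerKind, RasterLayer, RasterStack
from .preprocess import VifConfig, vif_stepwise

#: algorithms whose importance comes from leave-one-variable-out CV
LOO_ALGORITHMS = ("BIOCLIM", "DOMAIN", "MAXENT")

BUNDLE_VERSION = 1


class GateFailureError(RuntimeError):
    """No algorithm passed the goodness-of-fit gate; no ensemble possible."""


@dataclass(frozen=True)
class SelectionConfig:
    importance_min_pct: float = 5.0
    max_iterations: int = 10
    shape_screen: bool = True
    #: minimum CV AUC (best of the envelope/Maxent members) a trial variable
    #: set must reach for its newest variable to be retained — the
    #: predictive-power validation step of the selection loop
    skill_floor: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.importance_min_pct <= 100):
            raise ValueError("importance_min_pct must lie in [0, 100]")
        if not (0.5 <= self.skill_floor <= 1.0):
            raise ValueError("skill_floor must lie in [0.5, 1]")


# ---------------------------------------------------------------------------
# Importance

def relative_importance(raw: Mapping[str, float]) -> dict[str, float]:
    """Divide each raw importance by the total; results sum to one."""
    vals = np.array(list(raw.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("raw importances must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("total importance is zero")
    return {k: float(v / total) for k, v in raw.items()}


def loo_importance(algorithm: str, train: TrainingSet,
                   variables: Sequence[str], cv: CvConfig,
                   hyper=None, seed: int = 0) -> dict[str, float]:
    """Leave-one-variable-out importance: 1 - mean CV AUC without the variable.

    With a single variable the refit has no predictors; the no-predictor
    convention applies (AUC 0.5, importance 0.5).
    """
    out: dict[str, float] = {}
    for v in variables:
        rest = [w for w in variables if w != v]
        if not rest:
            out[v] = 0.5
            continue
        folds = ev.cross_validate(algorithm, train.subset_variables(rest),
                                  cv, hyper=hyper, seed=seed)
        out[v] = float(max(0.0, 1.0 - folds["auc"].mean()))
    return out


def _rescale(raw: dict[str, float]) -> dict[str, float]:
    """Rescale raw importances to [0, 1] by dividing by the maximum.

    Dividing by the maximum (rather than min-max) keeps the proportions
    between variables: min-max would map the weakest variable to exactly
    zero, which with two variables erases the newcomer's importance
    entirely.
    """
    vals = np.array(list(raw.values()), dtype=float)
    hi = vals.max()
    if hi <= 0:
        return {k: 1.0 for k in raw}
    return {k: float(v / hi) for k, v in raw.items()}


def importance_table(train: TrainingSet, cv: CvConfig,
                     algorithms: Sequence[str] = ALGORITHM_NAMES,
                     hyper: Mapping | None = None, seed: int = 0,
                     fitted: Mapping[str, alg.SdmModel] | None = None
                     ) -> pd.DataFrame:
    """Raw, min-max-rescaled and relative importance per variable/algorithm.

    Returns a frame indexed by variable with one raw column per algorithm,
    plus ``average`` (mean relative importance across algorithms, as a
    fraction), ``relative_pct`` (the same in percent) and ``dispersion``
    (standard deviation of the per-algorithm relative importances).
    """
    hyper = hyper or {}
    variables = train.variables
    per_alg_rel: dict[str, dict[str, float]] = {}
    raw_cols: dict[str, dict[str, float]] = {}
    cv_auc: dict[str, float] = {}
    for name in algorithms:
        if name in LOO_ALGORITHMS:
            full = ev.cross_validate(name, train, cv,
                                     hyper=hyper.get(name), seed=seed)
            cv_auc[name] = float(full["auc"].mean())
            if len(variables) >= 2:
                raw = loo_importance(name, train, variables, cv,
                                     hyper=hyper.get(name), seed=seed)
                # a label-independent variable's leave-one-out importance
                # tends to 1 - AUC of the full model, not 0; subtract that
                # null level before rescaling so the LOO scale is
                # commensurable with the native importances
                null_level = max(0.0, 1.0 - cv_auc[name])
                raw = {k: max(0.0, v - null_level) for k, v in raw.items()}
            else:
                raw = {variables[0]: 0.5}
        else:
            model = fitted[name] if fitted and name in fitted else \
                alg.fit(name, train, hyper=hyper.get(name), seed=seed)
            raw = model.native_importance()
        raw_cols[name] = raw
        scaled = _rescale(raw)
        total = sum(scaled.values())
        if total > 0:
            per_alg_rel[name] = {k: v / total for k, v in scaled.items()}
        else:
            per_alg_rel[name] = {k: 1.0 / len(scaled) for k in scaled}
    df = pd.DataFrame({a: raw_cols[a] for a in algorithms}).loc[variables]
    rel = pd.DataFrame({a: per_alg_rel[a] for a in algorithms}).loc[variables]
    df["average"] = rel.mean(axis=1)
    df["relative_pct"] = df["average"] * 100.0
    df["dispersion"] = rel.std(axis=1, ddof=1) if len(algorithms) > 1 else 0.0
    df.index.name = "variable"
    df.attrs["cv_auc"] = cv_auc
    return df


# ---------------------------------------------------------------------------
# Response curves

@dataclass
class ResponseCurve:
    variable: str
    grid: np.ndarray
    response: np.ndarray
    shape: str  # increasing | decreasing | unimodal | other
    flat: bool = False


def _classify_shape(curve: np.ndarray, flat_tol: float = 0.05,
                    r2_min: float = 0.6) -> tuple[str, bool]:
    """Label a response profile increasing / decreasing / unimodal / other.

    The rule emulates the eye-ball judgement of a plotted response: the
    (lightly smoothed) profile must be well described by a line or a
    downward parabola. Flat profiles (amplitude below ``flat_tol`` in
    absolute suitability units) and profiles no low-order trend explains
    (quadratic R^2 below ``r2_min``) are 'other', as is an interior valley
    (an upward parabola — the archetypal 'unexplainable' relationship).
    """
    n = len(curve)
    w = min(9, max(3, (n // 10) | 1))
    pad = np.pad(curve, w // 2, mode="edge")
    sm = np.convolve(pad, np.ones(w) / w, mode="valid")
    rng = sm.max() - sm.min()
    if rng < flat_tol:
        return "other", True
    z = np.linspace(0.0, 1.0, n)
    var = np.var(sm)

    def _r2(deg: int) -> tuple[np.ndarray, float]:
        coefs = np.polyfit(z, sm, deg)
        resid = sm - np.polyval(coefs, z)
        return coefs, 1.0 - np.var(resid) / var

    lin, r2_lin = _r2(1)
    quad, r2_quad = _r2(2)
    if r2_quad < r2_min:
        return "other", False
    if r2_quad - r2_lin <= 0.05 or abs(quad[0]) < 1e-12:
        return ("increasing" if lin[0] > 0 else "decreasing"), False
    vertex = -quad[1] / (2 * quad[0])
    if 0.05 <= vertex <= 0.95:
        if quad[0] < 0:
            return "unimodal", False
        return "other", False  # interior valley
    return ("increasing" if sm[-1] > sm[0] else "decreasing"), False


def response_curve(models: alg.SdmModel | Sequence[alg.SdmModel],
                   train: TrainingSet, variable: str,
                   n_grid: int = 100) -> ResponseCurve:
    """Mean-response profile of one variable, others at presence medians.

    The profile is the (median-ensemble) prediction along a 100-point grid
    spanning the variable's observed range, with every other variable held at
    its median over the presence rows. The shape label comes from the sign
    pattern of successive differences after light smoothing.
    """
    if hasattr(models, "predict"):
        models = [models]
    if variable not in train.variables:
        raise KeyError(f"variable {variable!r} not in the training set")
    col = train.X[variable].to_numpy(float)
    if col.min() == col.max():
        raise ValueError(f"variable {variable!r} is constant")
    grid = np.linspace(col.min(), col.max(), n_grid)
    med = train.presences().median()
    prof = pd.DataFrame({v: np.full(n_grid, med[v]) for v in train.variables})
    prof[variable] = grid
    preds = np.vstack([m.predict(prof) for m in models])
    curve = np.median(preds, axis=0)
    shape, flat = _classify_shape(curve)
    return ResponseCurve(variable=variable, grid=grid, response=curve,
                         shape=shape, flat=flat)


# ---------------------------------------------------------------------------
# Median ensemble

def ensemble_predict(members: Sequence[alg.SdmModel], stack: RasterStack,
                     variables: Sequence[str] | None = None,
                     name: str = "suitability") -> RasterLayer:
    """Cellwise median of member suitabilities over the stack's unmasked cells."""
    if not members:
        raise ValueError("no ensemble members")
    variables = list(variables or members[0].variables)
    sub = stack.subset(variables)
    mask = sub.combined_mask()
    idx = ~mask
    table = pd.DataFrame({v: sub[v].values[idx] for v in variables})
    preds = np.vstack([m.predict(table) for m in members])
    med = np.median(preds, axis=0)
    values = np.zeros(stack.grid.shape)
    values[idx] = med
    return RasterLayer(name=name, grid=stack.grid, values=values, mask=mask,
                       kind=LayerKind.CONTINUOUS)


def ensemble_predict_table(members: Sequence[alg.SdmModel],
                           X: pd.DataFrame) -> np.ndarray:
    if not members:
        raise ValueError("no ensemble members")
    return np.median(np.vstack([m.predict(X) for m in members]), axis=0)


def evaluate_ensemble(member_algorithms: Sequence[str], train: TrainingSet,
                      cv: CvConfig, hyper: Mapping | None = None,
                      seed: int = 0) -> dict:
    """CV of the median committee: members refit per fold, held-out medians.

    Returns mean AUC/TSS over folds, the fold table, and the max-TSS
    threshold computed on the pooled held-out median scores (the default
    binarization threshold).
    """
    hyper = hyper or {}
    rows = []
    pooled_scores, pooled_labels = [], []
    for rep, fold, tr, te in ev.cv_partitions(train.y, cv):
        y_te = train.y[te]
        if y_te.min() == y_te.max():
            continue
        sub = train.subset_rows(tr)
        members = [alg.fit(a, sub, hyper=hyper.get(a), seed=seed)
                   for a in member_algorithms]
        scores = ensemble_predict_table(members, train.X.iloc[te])
        t, _ = ev.tss_max(scores, y_te)
        rows.append({"repeat": rep, "fold": fold,
                     "auc": ev.auc(scores, y_te), "tss": t})
        pooled_scores.append(scores)
        pooled_labels.append(y_te)
    folds = pd.DataFrame(rows, columns=["repeat", "fold", "auc", "tss"])
    if folds.empty:
        raise ValueError("no usable CV folds for the ensemble")
    tss, threshold = ev.tss_max(np.concatenate(pooled_scores),
                                np.concatenate(pooled_labels))
    return {"auc": float(folds["auc"].mean()),
            "tss": float(folds["tss"].mean()),
            "threshold": float(threshold), "folds": folds}


def binarize(suitability: RasterLayer, threshold: float) -> RasterLayer:
    """Presence/absence layer: cell = 1 iff suitability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    values = (suitability.values >= threshold).astype(float)
    values[suitability.mask] = 0.0
    return RasterLayer(name=f"{suitability.name}_binary",
                       grid=suitability.grid, values=values,
                       mask=suitability.mask.copy(),
                       kind=LayerKind.CATEGORICAL)


# ---------------------------------------------------------------------------
# Forward selection

def forward_select(candidates: Sequence[str], train: TrainingSet,
                   cv: CvConfig, cfg: SelectionConfig | None = None,
                   algorithms: Sequence[str] = ALGORITHM_NAMES,
                   hyper: Mapping | None = None,
                   ) -> tuple[list[str], pd.DataFrame, list[dict]]:
    """Forward variable selection on average relative importance.

    One forward pass tries each candidate in order: the candidate joins the
    current set, every algorithm is refit, and the candidate is retained iff
    its average relative importance exceeds ``importance_min_pct`` percent
    and (when shape screening is on) its response-curve shape is not
    ``other``. Backward prune passes then drop any retained variable whose
    importance has fallen to or below the threshold, until stable or
    ``max_iterations``. Returns (selected, final importance table, audit log).
    """
    cfg = cfg or SelectionConfig()
    hyper = hyper or {}
    selected: list[str] = []
    audit: list[dict] = []

    def _step_table(names: list[str]) -> pd.DataFrame:
        sub = train.subset_variables(names)
        fitted = {a: alg.fit(a, sub, hyper=hyper.get(a), seed=cfg.seed)
                  for a in algorithms if a not in LOO_ALGORITHMS}
        table = importance_table(sub, cv, algorithms=algorithms, hyper=hyper,
                                 seed=cfg.seed, fitted=fitted)
        return table, sub, fitted

    last_context: dict[str, tuple] = {}
    for _pass in range(cfg.max_iterations):
        added_this_pass = False
        for cand in [c for c in candidates if c not in selected]:
            if last_context.get(cand) == tuple(selected):
                continue  # already rejected against this exact set
            last_context[cand] = tuple(selected)
            trial = selected + [cand]
            table, sub, fitted = _step_table(trial)
            pct = float(table.loc[cand, "relative_pct"])
            shape = None
            keep = pct > cfg.importance_min_pct
            # predictive-power validation: the trial combination must show
            # real CV skill (best of the cheap envelope/Maxent members)
            skill = max(table.attrs.get("cv_auc", {}).values(),
                        default=None)
            if keep and skill is not None:
                keep = skill >= cfg.skill_floor
            if keep and cfg.shape_screen:
                # screen on the discriminative members only: the envelope
                # algorithms' tent-shaped profiles (peaked at the presence
                # median by construction) would distort the committee median
                shape = response_curve(list(fitted.values()) or
                                       [alg.fit(a, sub,
                                                hyper=hyper.get(a),
                                                seed=cfg.seed)
                                        for a in algorithms],
                                       sub, cand).shape
                keep = shape != "other"
            audit.append({"action": "add" if keep else "reject",
                          "variable": cand, "relative_pct": pct,
                          "shape": shape, "cv_skill": skill,
                          "selected_after":
                          list(trial if keep else selected)})
            if keep:
                selected = trial
                added_this_pass = True
        if not added_this_pass:
            break

    # backward prune: drop the weakest variable while any falls at/below
    # the importance threshold
    table = None
    for _ in range(cfg.max_iterations):
        if len(selected) == 0:
            break
        table = _step_table(selected)[0]
        weak = table.loc[selected][table.loc[selected, "relative_pct"]
                                   <= cfg.importance_min_pct]
        if weak.empty or len(selected) == 1:
            break
        victim = weak["relative_pct"].idxmin()
        selected.remove(victim)
        audit.append({"action": "drop", "variable": victim,
                      "relative_pct": float(weak.loc[victim, "relative_pct"]),
                      "shape": None, "selected_after": list(selected)})
        table = None

    if not selected:
        audit.append({"action": "flag", "variable": None,
                      "relative_pct": None, "shape": None,
                      "selected_after": []})
        return [], pd.DataFrame(), audit
    if table is None:
        table = _step_table(selected)[0]
    return selected, table, audit


# ---------------------------------------------------------------------------
# Model / Results

class EnsembleSDM:
    """Ensemble species-distribution model for one presence-background table.

    Parameters
    ----------
    train : TrainingSet
        Covariate table and binary labels (1 = presence/carcass,
        0 = background).
    candidates : sequence of str, optional
        Variables offered to selection (default: every column).
    vif, selection, cv, gate : configuration dataclasses.
    algorithms : algorithms to fit (default: all eight).
    hyper : per-algorithm hyperparameter overrides.
    """

    def __init__(self, train: TrainingSet,
                 candidates: Sequence[str] | None = None, *,
                 vif: VifConfig | None = None,
                 selection: SelectionConfig | None = None,
                 cv: CvConfig | None = None,
                 gate: GateConfig | None = None,
                 algorithms: Sequence[str] = ALGORITHM_NAMES,
                 hyper: Mapping | None = None,
                 seed: int = 0):
        self.train = train
        self.candidates = list(candidates or train.variables)
        self.vif = vif or VifConfig()
        self.selection = selection or SelectionConfig(seed=seed)
        self.cv = cv or CvConfig(seed=seed)
        self.gate = gate or GateConfig()
        self.algorithms = list(algorithms)
        self.hyper = dict(hyper or {})
        self.seed = int(seed)

    @classmethod
    def from_stack(cls, stack: RasterStack, presences, background,
                   candidates: Sequence[str] | None = None, **kwargs
                   ) -> "EnsembleSDM":
        """Build the training table by extracting the stack at point sets."""
        from .grids import extract_at_points

        frames, labels = [], []
        for pts, lab in ((presences, 1), (background, 0)):
            df = extract_at_points(stack, pts)
            df = df[~df["any_masked"]].drop(columns="any_masked")
            frames.append(df)
            labels.append(np.full(len(df), lab))
        X = pd.concat(frames, ignore_index=True)
        y = np.concatenate(labels)
        train = TrainingSet(X, y, dict(stack.kinds()))
        return cls(train, candidates=candidates, **kwargs)

    def fit(self) -> "EnsembleSDMResults":
        """Run VIF screening, forward selection, the gate and the ensemble."""
        retained, vif_excluded = vif_stepwise(self.train.X[self.candidates],
                                              self.vif)
        selected, imp_all, audit = forward_select(
            retained, self.train, self.cv, self.selection,
            algorithms=self.algorithms, hyper=self.hyper)
        if not selected:
            raise GateFailureError("forward selection retained no variable")
        sub = self.train.subset_variables(selected)
        folds = {a: ev.cross_validate(a, sub, self.cv,
                                      hyper=self.hyper.get(a), seed=self.seed)
                 for a in self.algorithms}
        report = ev.summarize_cv(folds)
        admitted = report.admitted(self.gate)
        results = EnsembleSDMResults(
            model=self, variables=selected, vif_excluded=vif_excluded,
            cv_report=report, admitted=admitted, audit_log=audit)
        if not admitted:
            results.gate_failed = True
            return results
        members = [alg.fit(a, sub, hyper=self.hyper.get(a), seed=self.seed)
                   for a in admitted]
        ens = evaluate_ensemble(admitted, sub, self.cv, hyper=self.hyper,
                                seed=self.seed)
        fitted = {m.algorithm: m for m in members
                  if m.algorithm not in LOO_ALGORITHMS}
        results.members = members
        results.importance = importance_table(
            sub, self.cv, algorithms=admitted, hyper=self.hyper,
            seed=self.seed, fitted=fitted)
        results.ensemble_auc = ens["auc"]
        results.ensemble_tss = ens["tss"]
        results.threshold = ens["threshold"]
        results.ensemble_folds = ens["folds"]
        return results


@dataclass
class EnsembleSDMResults:
    """Fitted ensemble: members, selection outcome, metrics and predictions."""

    model: EnsembleSDM
    variables: list[str]
    vif_excluded: list[str]
    cv_report: CvReport
    admitted: list[str]
    audit_log: list[dict]
    members: list[alg.SdmModel] = field(default_factory=list)
    importance: pd.DataFrame | None = None
    ensemble_auc: float | None = None
    ensemble_tss: float | None = None
    threshold: float | None = None
    ensemble_folds: pd.DataFrame | None = None
    gate_failed: bool = False

    def require_members(self) -> None:
        if self.gate_failed or not self.members:
            raise GateFailureError(
                "no algorithm passed the goodness-of-fit gate "
                f"(AUC >= {self.model.gate.auc_min}, "
                f"TSS >= {self.model.gate.tss_min})")

    def predict_stack(self, stack: RasterStack, name: str = "suitability"
                      ) -> RasterLayer:
        self.require_members()
        return ensemble_predict(self.members, stack, self.variables, name)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self.require_members()
        return ensemble_predict_table(self.members, X)

    def binary_map(self, stack: RasterStack, threshold: float | None = None
                   ) -> RasterLayer:
        suit = self.predict_stack(stack)
        return binarize(suit, self.threshold if threshold is None
                        else threshold)

    def response(self, variable: str) -> ResponseCurve:
        self.require_members()
        sub = self.model.train.subset_variables(self.variables)
        return response_curve(self.members, sub, variable)

    def summary(self) -> str:
        lines = ["Ensemble species distribution model", "=" * 38]
        lines.append(f"candidates offered : {len(self.model.candidates)}")
        lines.append(f"VIF-excluded       : {self.vif_excluded}")
        lines.append(f"selected variables : {self.variables}")
        lines.append("")
        lines.append(self.cv_report.with_verdicts(self.model.gate)
                     .to_string(index=False,
                                float_format=lambda v: f"{v:.3f}"))
        if self.gate_failed:
            lines.append("\nGATE FAILURE: no algorithm admitted; "
                         "no ensemble built.")
            return "\n".join(lines)
        lines.append("")
        lines.append(f"ensemble members   : {self.admitted}")
        lines.append(f"ensemble AUC       : {self.ensemble_auc:.3f}")
        lines.append(f"ensemble TSS       : {self.ensemble_tss:.3f}")
        lines.append(f"max-TSS threshold  : {self.threshold:.3f}")
        if self.importance is not None:
            lines.append("\nVariable importance (relative %):")
            lines.append(self.importance[["average", "relative_pct",
                                          "dispersion"]]
                         .to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Write a versioned results bundle (Python pickle, version-tagged)."""
        with open(path, "wb") as fh:
            pickle.dump({"version": BUNDLE_VERSION, "results": self}, fh)

    @classmethod
    def load(cls, path) -> "EnsembleSDMResults":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if obj.get("version") != BUNDLE_VERSION:
            raise ValueError(f"unsupported bundle version {obj.get('version')}")
        return obj["results"]
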