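"""Repeated stratified cross-validation, AUC/TSS scoring and the ensemble gate.

AUC is the Mann-Whitney statistic (ties half-counted). TSS is maximized over
the finite set of thresholds that matter: midpoints between adjacent distinct
scores plus sentinels below and above every score. Algorithms enter the
ensemble when their CV means pass the goodness-of-fit gate
(AUC >= 0.80 and TSS >= 0.60, closed bounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import algorithms as alg


@dataclass(frozen=True)
class CvConfig:
    k: int = 10
    n_repeats: int = 50
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


@dataclass(frozen=True)
class GateConfig:
    auc_min: float = 0.80
    tss_min: float = 0.60

    def __post_init__(self) -> None:
        if not (0.5 <= self.auc_min <= 1.0):
            raise ValueError("auc_min must lie in [0.5, 1]")
        if not (0.0 <= self.tss_min <= 1.0):
            raise ValueError("tss_min must lie in [0, 1]")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one case of each class")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def tss_max(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Maximum of sensitivity + specificity - 1 over all thresholds.

    A site is classed positive when its score >= threshold. Candidate
    thresholds are midpoints of adjacent distinct scores plus sentinels below
    the minimum and above the maximum score; ties in TSS go to the larger
    threshold. Returns (tss, threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("TSS needs at least one case of each class")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    span = max(uniq[-1] - uniq[0], 1.0)
    cand = np.concatenate([[uniq[0] - span], mids, [uniq[-1] + span]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] >= cand[:, None]).sum(axis=1) / n_pos
    spec = (neg[None, :] < cand[:, None]).sum(axis=1) / n_neg
    tss = sens + spec - 1.0
    best = np.flatnonzero(tss == tss.max())[-1]  # larger threshold on ties
    return float(tss[best]), float(cand[best])


@dataclass
class CvReport:
    """Per-algorithm CV summary plus the gate verdict."""

    table: pd.DataFrame  # algorithm, auc_mean, auc_se, tss_mean, tss_se, ...

    def admitted(self, cfg: GateConfig | None = None) -> list[str]:
        cfg = cfg or GateConfig()
        ok = (self.table["auc_mean"] >= cfg.auc_min) & \
             (self.table["tss_mean"] >= cfg.tss_min)
        return list(self.table.loc[ok, "algorithm"])

    def with_verdicts(self, cfg: GateConfig | None = None) -> pd.DataFrame:
        adm = set(self.admitted(cfg))
        out = self.table.copy()
        out["admitted"] = out["algorithm"].isin(adm)
        return out

    def to_csv(self, path, cfg: GateConfig | None = None) -> None:
        self.with_verdicts(cfg).to_csv(path, index=False)


def cv_partitions(y: np.ndarray, cv: CvConfig):
    """Yield (repeat, fold, train_idx, test_idx) for every repeated fold."""
    y = np.asarray(y, dtype=int)
    if cv.stratified:
        counts = np.bincount(y, minlength=2)
        if counts.min() < cv.k:
            raise ValueError(
                f"stratified {cv.k}-fold CV needs >= {cv.k} rows of each "
                f"class (have {counts.min()})"
            )
    ss = np.random.SeedSequence(cv.seed)
    for rep, child in enumerate(ss.spawn(cv.n_repeats)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        if cv.stratified:
            splitter = StratifiedKFold(n_splits=cv.k, shuffle=True,
                                       random_state=rep_seed)
            splits = splitter.split(np.zeros(len(y)), y)
        else:
            rng = np.random.default_rng(rep_seed)
            order = rng.permutation(len(y))
            splits = ((np.setdiff1d(order, part), part)
                      for part in np.array_split(order, cv.k))
        for fold, (tr, te) in enumerate(splits):
            yield rep, fold, tr, te


def cross_validate(algorithm: str, train: "alg.TrainingSet", cv: CvConfig,
                   hyper=None, seed: int = 0) -> pd.DataFrame:
    """Fold-level AUC/TSS for one algorithm under repeated stratified CV.

    Unstratified folds that end up single-class are skipped (their count is
    recorded in ``df.attrs['n_skipped']``). Deterministic for a given CvConfig.
    """
    rows = []
    n_skipped = 0
    for rep, fold, tr, te in cv_partitions(train.y, cv):
        y_te = train.y[te]
        if y_te.min() == y_te.max():
            n_skipped += 1
            continue
        model = alg.fit(algorithm, train.subset_rows(tr), hyper=hyper,
                        seed=seed)
        scores = model.predict(train.X.iloc[te])
        t, _ = tss_max(scores, y_te)
        rows.append({"repeat": rep, "fold": fold,
                     "auc": auc(scores, y_te), "tss": t})
    df = pd.DataFrame(rows, columns=["repeat", "fold", "auc", "tss"])
    df.attrs["n_skipped"] = n_skipped
    return df


def summarize_cv(per_algorithm: dict[str, pd.DataFrame]) -> CvReport:
    """Fold scores -> mean and standard error over all k x n_repeats folds."""
    rows = []
    for name, folds in per_algorithm.items():
        n = len(folds)
        rows.append({
            "algorithm": name,
            "auc_mean": folds["auc"].mean(),
            "auc_se": folds["auc"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "tss_mean": folds["tss"].mean(),
            "tss_se": folds["tss"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "n_folds": n,
        })
    return CvReport(pd.DataFrame(rows))


def gate(report: CvReport, cfg: GateConfig | None = None) -> list[str]:
    """Algorithms whose CV means pass the goodness-of-fit gate."""
    if report.table.empty:
        raise ValueError("empty CV report")
    return report.admitted(cfg)
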