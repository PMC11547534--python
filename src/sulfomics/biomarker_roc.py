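"""Univariate biomarker statistics and random-forest MCCV evaluation.

A selected feature panel (normalized, imputed areas) is evaluated in two
ways:

* **Univariate** — per feature: rank-based AUC (Mann–Whitney U divided by
  n1·n2, ties counted half, oriented to >= 0.5), a two-sided Welch t-test
  on log2 areas, the IM-vs-oral log2 fold change, and co-behaviour cluster
  IDs from average-linkage hierarchical clustering of 1 − |Spearman ρ|.
* **Multivariate** — Monte-Carlo cross-validation: repeated stratified
  2/3 train / 1/3 holdout splits, a random forest per split, holdout
  class-probability scores pooled into one ROC, a 95% percentile band
  over the per-run AUCs, permutation (mean-decrease-in-accuracy) feature
  importances, and a confusion matrix from per-sample majority votes over
  the runs in which each sample was held out.

IM administration is the positive class, oral the negative class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledMatrix",
    "MccvConfig",
    "ConfusionMatrix",
    "MccvReport",
    "univariate_auc",
    "univariate_stats",
    "mccv_rf",
    "sensitivity_specificity",
]


@dataclass
class LabeledMatrix:
    """Samples x selected features with a binary class per sample
    (True = IM = positive, False = oral = negative)."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y indexed by different samples")
        if self.X.isna().any().any():
            raise ValueError("missing values; impute before modelling")
        self.y = self.y.astype(bool)
        if int(self.y.sum()) < 2 or int((~self.y).sum()) < 2:
            raise ValueError("need at least 2 samples per class")


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> Tuple[float, int]:
    """Rank-based AUC for one feature, oriented to >= 0.5.

    Equals the Mann–Whitney U statistic divided by n1·n2 with ties counted
    half.  Returns (AUC, direction): direction +1 when the positive class
    sits higher, −1 when the orientation was flipped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    if auc >= 0.5:
        return float(auc), 1
    return float(1.0 - auc), -1


def univariate_stats(m: LabeledMatrix, n_clusters: Optional[int] = None) -> pd.DataFrame:
    """Per-feature AUC, Welch-t p, log2FC and co-behaviour cluster ID."""
    y = m.y.to_numpy()
    rows = []
    for feat in m.X.columns:
        v = m.X[feat].to_numpy(dtype=float)
        if np.all(v == v[0]):
            logger.warning("univariate_stats: feature %s is constant", feat)
            rows.append((feat, 0.5, 0, 1.0, 0.0))
            continue
        auc, direction = univariate_auc(v, y)
        lv = np.log2(np.maximum(v, np.finfo(float).tiny))
        p = float(stats.ttest_ind(lv[y], lv[~y], equal_var=False).pvalue)
        log2fc = float(np.log2(v[y].mean()) - np.log2(v[~y].mean()))
        rows.append((feat, auc, direction, p, log2fc))
    out = pd.DataFrame(
        rows, columns=["feature", "auc", "direction", "p", "log2fc"]
    ).set_index("feature")

    k = len(m.X.columns)
    if n_clusters is None:
        n_clusters = min(4, k)
    if k == 1:
        out["cluster"] = 1
        return out
    rho = m.X.corr(method="spearman").to_numpy()
    rho[np.isnan(rho)] = 0.0  # constant features: no co-behaviour signal
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    out["cluster"] = fcluster(Z, t=n_clusters, criterion="maxclust")
    return out


@dataclass(frozen=True)
class MccvConfig:
    """Monte-Carlo cross-validation settings."""

    runs: int = 30
    train_fraction: float = 2.0 / 3.0
    trees: int = 300
    seed: int = 0
    importance_repeats: int = 5

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")
        if self.trees < 1:
            raise ValueError("trees must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MccvReport:
    """Pooled ROC, AUC with 95% band, votes, importances, per-run AUCs."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    run_aucs: np.ndarray
    confusion: ConfusionMatrix
    importances: pd.Series
    votes: pd.DataFrame  # per sample: n_holdout, n_positive_votes, predicted
    config: MccvConfig


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    train_idx: List[int] = []
    for cls in (False, True):
        idx = np.nonzero(y == cls)[0]
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides keep the class
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
    train = np.zeros(y.size, dtype=bool)
    train[train_idx] = True
    return train


def mccv_rf(m: LabeledMatrix, cfg: MccvConfig = MccvConfig()) -> MccvReport:
    """Random-forest MCCV evaluation of a feature panel.

    No scaling or transformation is applied to the areas.  Splits are
    stratified so every holdout contains both classes.  The per-sample
    predicted class is the majority vote over the runs in which the sample
    was held out; a vote fraction of exactly 0.5 (or a sample never held
    out, which is vanishingly rare at 30 runs) counts as positive.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance
    from sklearn.metrics import auc as _trapezoid_auc, roc_curve

    X = m.X.to_numpy(dtype=float)
    y = m.y.to_numpy()
    rng = np.random.default_rng(cfg.seed)
    pooled_scores: List[float] = []
    pooled_truth: List[bool] = []
    run_aucs = np.empty(cfg.runs)
    n = y.size
    n_holdout = np.zeros(n, dtype=int)
    n_pos_votes = np.zeros(n, dtype=int)
    importance_sum = np.zeros(X.shape[1])
    for run in range(cfg.runs):
        train = _stratified_split(y, cfg.train_fraction, rng)
        test = ~train
        rf = RandomForestClassifier(
            n_estimators=cfg.trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        ).fit(X[train], y[train])
        scores = rf.predict_proba(X[test])[:, list(rf.classes_).index(True)]
        pooled_scores.extend(scores.tolist())
        pooled_truth.extend(y[test].tolist())
        fpr_r, tpr_r, _ = roc_curve(y[test], scores)
        run_aucs[run] = _trapezoid_auc(fpr_r, tpr_r)
        n_holdout[test] += 1
        n_pos_votes[test] += (scores >= 0.5).astype(int)
        imp = permutation_importance(
            rf, X[test], y[test],
            n_repeats=cfg.importance_repeats,
            random_state=int(rng.integers(0, 2**31 - 1)),
            scoring="accuracy",
        )
        importance_sum += imp.importances_mean

    never = n_holdout == 0
    if never.any():
        logger.warning("mccv_rf: %d samples never held out; counted as positive votes", int(never.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_holdout > 0, n_pos_votes / np.maximum(n_holdout, 1), 0.5)
    predicted = frac >= 0.5  # tie -> positive

    fpr, tpr, _ = roc_curve(pooled_truth, pooled_scores)
    pooled_auc = float(_trapezoid_auc(fpr, tpr))
    ci_low, ci_high = np.percentile(run_aucs, [2.5, 97.5])
    cm = ConfusionMatrix(
        tp=int(np.sum(predicted & y)),
        fn=int(np.sum(~predicted & y)),
        fp=int(np.sum(predicted & ~y)),
        tn=int(np.sum(~predicted & ~y)),
    )
    votes = pd.DataFrame(
        {"n_holdout": n_holdout, "n_positive_votes": n_pos_votes, "predicted_im": predicted},
        index=m.X.index,
    )
    importances = pd.Series(importance_sum / cfg.runs, index=m.X.columns, name="mean_decrease_accuracy")
    return MccvReport(
        fpr=fpr, tpr=tpr, auc=pooled_auc,
        ci_low=float(ci_low), ci_high=float(ci_high),
        run_aucs=run_aucs, confusion=cm,
        importances=importances, votes=votes, config=cfg,
    )


def sensitivity_specificity(cm: ConfusionMatrix) -> Tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) from a confusion matrix.

    Exact percentages are returned; round to the nearest integer for
    report-style display.
    """
    if cm.tp + cm.fn == 0 or cm.fp + cm.tn == 0:
        raise ValueError("confusion matrix has an empty actual class")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn)
    spec = 100.0 * cm.tn / (cm.tn + cm.fp)
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return sens, spec, acc
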