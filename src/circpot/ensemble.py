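"""Cross-validation forest ensembles with fractile-score aggregation and
false-positive-rate calibration.

Training runs a stratified five-fold cross validation; each fold fits a
random forest of unpruned trees on the other four folds and keeps the
held-out fold's positive-class score distribution. At prediction time each
of the five forests scores the input, the score is converted to a fractile
(quantile position, ties at half weight) within that fold's validation
score distribution, and the five fractiles are averaged — rank aggregation
across the ensemble. An FPR table maps mean-fractile cutoffs to the
fraction of held-out negatives scoring at or above the cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

DEFAULT_TREE_GRID = tuple(range(10, 101, 10))
DEFAULT_CUTOFFS = np.round(np.linspace(0.0, 1.0, 101), 10)

# Paper-calibrated tree counts for the three shipped classifiers.
MODEL_TREES = {"cp-pcg": 80, "cp-lncrna": 100, "sp-circrna": 60}


def auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties 0.5).

    The Mann-Whitney form of the area under the ROC curve.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc requires non-empty positive and negative scores")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def score_to_fractile(score: float, val_scores: Sequence[float]) -> float:
    """Fractile of a score within a validation score distribution.

    ``(#{v < s} + 0.5 * #{v == s}) / n`` — ties get half weight, so the
    fractiles of a distribution against itself are uniform on (0, 1).
    """
    vs = np.asarray(val_scores, dtype=float)
    if vs.size == 0:
        raise ValueError("empty validation score distribution")
    vs = np.sort(vs)
    lo = np.searchsorted(vs, score, side="left")
    hi = np.searchsorted(vs, score, side="right")
    return float((lo + 0.5 * (hi - lo)) / vs.size)


def _fractiles_vec(scores: np.ndarray, sorted_val: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(sorted_val, scores, side="left")
    hi = np.searchsorted(sorted_val, scores, side="right")
    return (lo + 0.5 * (hi - lo)) / sorted_val.size


@dataclass
class CalibrationTable:
    """Mean-fractile cutoff -> estimated FPR on held-out negatives."""

    cutoffs: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        if self.cutoffs.size != self.fpr.size or self.cutoffs.size == 0:
            raise ValueError("cutoffs and fpr must be equal-length, non-empty")
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly ascending")
        if np.any(np.diff(self.fpr) > 1e-12):
            raise ValueError("fpr must be non-increasing in the cutoff")

    def lookup(self, mean_fractile) -> np.ndarray:
        """Step-function lookup: FPR at the largest tabulated cutoff <= query."""
        q = np.asarray(mean_fractile, dtype=float)
        idx = np.searchsorted(self.cutoffs, q, side="right") - 1
        idx = np.clip(idx, 0, self.cutoffs.size - 1)
        out = self.fpr[idx]
        # queries below the first tabulated cutoff see every negative above them
        out = np.where(q < self.cutoffs[0], 1.0, out)
        return out if out.ndim else float(out)

    def to_json(self) -> str:
        return json.dumps({"cutoffs": self.cutoffs.tolist(),
                           "fpr": self.fpr.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "CalibrationTable":
        obj = json.loads(text)
        return cls(np.asarray(obj["cutoffs"]), np.asarray(obj["fpr"]))


def calibrate_fpr(neg_mean_fractiles: Sequence[float],
                  cutoffs: Optional[np.ndarray] = None) -> CalibrationTable:
    """Build the FPR table from negative mean fractiles.

    ``fpr(t) = #{f >= t} / n`` on the held-out negative scores; the table is
    monotone non-increasing with ``fpr(0) = 1``.
    """
    f = np.asarray(neg_mean_fractiles, dtype=float)
    if f.size == 0:
        raise ValueError("calibrate_fpr requires non-empty negatives")
    if cutoffs is None:
        cutoffs = DEFAULT_CUTOFFS
    cutoffs = np.asarray(cutoffs, dtype=float)
    fpr = np.array([(f >= t).mean() for t in cutoffs])
    return CalibrationTable(cutoffs=cutoffs, fpr=fpr)


@dataclass
class PredictionResult:
    """Per-input prediction: raw fold scores, fractiles, their mean, FPR."""

    id: str
    raw_scores: np.ndarray
    fractiles: np.ndarray
    mean_fractile: float
    fpr: Optional[float] = None


class FractileForestClassifier(ClassifierMixin, BaseEstimator):
    """Stratified K-fold random-forest ensemble scored by mean fractile.

    Parameters
    ----------
    n_estimators : int, default 100
        Trees per fold forest (unpruned; bootstrap sampling leaves about a
        third of rows out-of-bag per tree).
    n_folds : int, default 5
        Cross-validation folds; one forest per fold.
    random_state : int or None
        Seeds the fold split and every fold forest; fixed seed gives
        bit-for-bit reproducible ensembles and predictions.

    Attributes
    ----------
    models_ : list of fitted RandomForestClassifier, one per fold.
    fold_assignment_ : array mapping each training row to its fold.
    val_scores_ : list of ascending arrays; fold k's held-out scores.
    oof_scores_ : pooled out-of-fold positive-class scores per row.
    cv_auc_ : pooled out-of-fold AUC on the training data.
    calibration_ : CalibrationTable, present after :meth:`calibrate`.
    """

    def __init__(self, n_estimators: int = 100, n_folds: int = 5,
                 random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.n_folds = n_folds
        self.random_state = random_state

    def _fold_seed(self, k: int) -> Optional[int]:
        if self.random_state is None:
            return None
        return (int(self.random_state) * 1009 + 7 * k + 1) % (2 ** 31)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"need exactly two classes, got {classes.tolist()}")
        if X.shape[0] < 2 * self.n_folds:
            raise ValueError("too few rows for the requested fold count")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        y_bin = (y == classes[1]).astype(int)

        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.random_state)
        self.models_ = []
        self.val_scores_ = []
        self.fold_assignment_ = np.empty(X.shape[0], dtype=int)
        self.oof_scores_ = np.empty(X.shape[0], dtype=float)
        fold_aucs = []
        for k, (train_idx, val_idx) in enumerate(skf.split(X, y_bin)):
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self._fold_seed(k),
                n_jobs=1)
            forest.fit(X[train_idx], y_bin[train_idx])
            scores = forest.predict_proba(X[val_idx])[:, 1]
            self.models_.append(forest)
            self.val_scores_.append(np.sort(scores))
            self.fold_assignment_[val_idx] = k
            self.oof_scores_[val_idx] = scores
            yv = y_bin[val_idx]
            if yv.min() != yv.max():
                fold_aucs.append(auc(scores[yv == 1], scores[yv == 0]))
        self.fold_aucs_ = np.asarray(fold_aucs)
        self.cv_auc_ = auc(self.oof_scores_[y_bin == 1],
                           self.oof_scores_[y_bin == 0])
        return self

    def raw_scores(self, X) -> np.ndarray:
        """n x n_folds matrix of per-fold positive-class probabilities."""
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns, "
                f"model expects {self.n_features_in_}")
        return np.column_stack([m.predict_proba(X)[:, 1]
                                for m in self.models_])

    def fractile_scores(self, X) -> np.ndarray:
        """n x n_folds matrix of per-fold fractiles."""
        raw = self.raw_scores(X)
        return np.column_stack([
            _fractiles_vec(raw[:, k], self.val_scores_[k])
            for k in range(len(self.models_))])

    def predict_mean_fractile(self, X) -> np.ndarray:
        return self.fractile_scores(X).mean(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        mf = self.predict_mean_fractile(X)
        return np.column_stack([1.0 - mf, mf])

    def predict(self, X) -> np.ndarray:
        mf = self.predict_mean_fractile(X)
        return self.classes_[(mf >= 0.5).astype(int)]

    def calibrate(self, X_neg=None, neg_mean_fractiles=None,
                  cutoffs: Optional[np.ndarray] = None):
        """Attach an FPR table estimated on held-out negatives."""
        check_is_fitted(self, "models_")
        if neg_mean_fractiles is None:
            if X_neg is None:
                raise ValueError("supply X_neg or neg_mean_fractiles")
            neg_mean_fractiles = self.predict_mean_fractile(X_neg)
        self.calibration_ = calibrate_fpr(neg_mean_fractiles, cutoffs)
        return self


def train_cv_ensemble(X, y, n_trees: int = 100,
                      seed: Optional[int] = None,
                      n_folds: int = 5) -> FractileForestClassifier:
    """Functional wrapper: fit a stratified K-fold forest ensemble."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("train_cv_ensemble requires at least 10 rows")
    return FractileForestClassifier(
        n_estimators=n_trees, n_folds=n_folds, random_state=seed).fit(X, y)


def cv_auc(X, y, n_trees: int, seed: Optional[int] = None,
           n_folds: int = 5) -> float:
    """Mean per-fold cross-validated AUC at a given tree count."""
    model = FractileForestClassifier(
        n_estimators=n_trees, n_folds=n_folds, random_state=seed).fit(X, y)
    return float(model.fold_aucs_.mean())


def tune_num_trees(X, y, grid: Sequence[int] = DEFAULT_TREE_GRID,
                   seed: Optional[int] = None, n_folds: int = 5) -> int:
    """Pick the tree count with the highest mean CV AUC (ties -> smallest)."""
    grid = list(grid)
    if not grid:
        raise ValueError("tune_num_trees requires a non-empty grid")
    best_t, best_auc = None, -np.inf
    for t in sorted(grid):
        a = cv_auc(X, y, n_trees=t, seed=seed, n_folds=n_folds)
        if a > best_auc:
            best_t, best_auc = t, a
    return best_t


def predict(records_ids: Sequence[str], X,
            ensemble: FractileForestClassifier,
            calibration: Optional[CalibrationTable] = None,
            ) -> List[PredictionResult]:
    """Score feature vectors through the ensemble and FPR table."""
    if calibration is None:
        calibration = getattr(ensemble, "calibration_", None)
    raw = ensemble.raw_scores(X)
    fracs = ensemble.fractile_scores(X)
    mean_f = fracs.mean(axis=1)
    results = []
    for i, rid in enumerate(records_ids):
        fpr = None if calibration is None else float(calibration.lookup(mean_f[i]))
        results.append(PredictionResult(
            id=rid, raw_scores=raw[i], fractiles=fracs[i],
            mean_fractile=float(mean_f[i]), fpr=fpr))
    return results


def permutation_importance(forest: RandomForestClassifier, X, y,
                           seed: Optional[int] = None) -> np.ndarray:
    """Per-tree out-of-bag permutation importance.

    For each tree, its OOB rows (rows absent from the tree's bootstrap) give
    a baseline misclassification error; each feature is then shuffled over
    the OOB rows and the error recomputed. The importance of a feature is
    the increase in OOB error averaged over trees. Trees with no OOB rows
    are skipped with a warning.
    """
    check_is_fitted(forest, "estimators_")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    diffs = []
    for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        oob = np.flatnonzero(oob_mask)
        if oob.size == 0:
            warnings.warn("tree with no out-of-bag rows skipped")
            continue
        X_oob, y_oob = X[oob], y[oob]
        pred = forest.classes_[tree.predict(X_oob).astype(int)]
        base_err = float(np.mean(pred != y_oob))
        row = np.empty(p)
        for j in range(p):
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            pred = forest.classes_[tree.predict(Xp).astype(int)]
            row[j] = float(np.mean(pred != y_oob)) - base_err
        diffs.append(row)
    if not diffs:
        raise ValueError("no tree had out-of-bag rows")
    return np.mean(diffs, axis=0)
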