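"""Repeated cross-validated classification on selected features.

Logistic regression, an RBF-kernel SVM and a random forest are evaluated
under repeated stratified 5-fold cross-validation.  Feature selection runs
inside the training folds only; the held-out fold is scored with the
training-fold model and AUC / PPV / NPV are averaged over folds x repeats.
Counts are log2(count+1)-transformed and standardised with training-fold
statistics before reaching a classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import selectors
from .simdata import LabeledCountMatrix

__all__ = ["ClassifierReport", "repeated_cv", "svm_rbf", "auc", "ppv_npv",
           "CLASSIFIER_IDS"]

log = logging.getLogger(__name__)

CLASSIFIER_IDS = ("logistic", "svm", "rf")


@dataclass
class ClassifierReport:
    dataset_id: str
    fs_method: str
    classifier: str
    auc: float
    ppv: float
    npv: float
    n_repeats: int
    n_folds: int
    selection_frequency: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "dataset_id": self.dataset_id, "fs_method": self.fs_method,
            "classifier": self.classifier, "auc": self.auc,
            "ppv": self.ppv, "npv": self.npv,
        }])


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the tie-corrected rank statistic: the
    probability a positive sample outscores a negative one, counting ties
    as one half."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, float)
    n1, n0 = int(labels.sum()), int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def ppv_npv(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Positive and negative predictive values of hard class predictions
    (NaN when a predicted class is empty)."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    tp = np.sum((predictions == 1) & (labels == 1))
    fp = np.sum((predictions == 1) & (labels == 0))
    tn = np.sum((predictions == 0) & (labels == 0))
    fn = np.sum((predictions == 0) & (labels == 1))
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return float(ppv), float(npv)


def _transform(train_counts: np.ndarray, test_counts: np.ndarray):
    """log2(x+1) then standardise using training-fold statistics only."""
    tr = np.log2(train_counts.astype(float) + 1.0).T
    te = np.log2(test_counts.astype(float) + 1.0).T
    mu, sd = tr.mean(axis=0), tr.std(axis=0)
    sd[sd == 0] = 1.0
    return (tr - mu) / sd, (te - mu) / sd


def svm_rbf(
    train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
    gamma: float = 3.0, C: float = 1.0, epsilon: float | None = None,
) -> np.ndarray:
    """Soft-margin RBF-kernel SVM decision values on standardised inputs.

    ``epsilon`` belongs to the regression form of the SVM and is accepted
    but ignored (with a warning) in this classification setting.
    """
    if epsilon is not None:
        warnings.warn("epsilon applies to SVM regression; ignored for "
                      "classification", stacklevel=2)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training fold contains a single class")
    model = SVC(kernel="rbf", gamma=gamma, C=C)
    model.fit(train_X, np.asarray(train_y).astype(int))
    return model.decision_function(test_X)


def _fit_score(classifier: str, train_X, train_y, test_X, seed: int):
    """Returns (continuous scores, hard predictions) on the held-out fold."""
    if classifier == "logistic":
        # near-unpenalised ML with a tiny ridge for solvability; iteration
        # capped — non-convergence in the p >> n regime is expected and
        # intentionally tolerated
        model = LogisticRegression(C=1e8, max_iter=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(train_X, train_y)
        score = model.decision_function(test_X)
        return score, (score > 0).astype(int)
    if classifier == "svm":
        score = svm_rbf(train_X, train_y, test_X)
        return score, (score > 0).astype(int)
    if classifier == "rf":
        model = RandomForestClassifier(n_estimators=500, random_state=seed)
        model.fit(train_X, train_y)
        prob = model.predict_proba(test_X)[:, list(model.classes_).index(1)]
        return prob, (prob > 0.5).astype(int)
    raise ValueError(f"unknown classifier {classifier!r}; choose from {CLASSIFIER_IDS}")


def repeated_cv(
    data: LabeledCountMatrix,
    fs_method: str,
    classifier: str,
    n_folds: int = 5,
    n_repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
    fs_params: dict | None = None,
    dataset_id: str = "dataset",
) -> ClassifierReport:
    """Repeated stratified n-fold CV with in-fold feature selection.

    Per repeat a fresh stratified fold assignment is drawn; the selector
    runs on the training folds only, the classifier is fit on the selected
    features and scored on the held-out fold.  If a selector returns an
    empty set the single best-scoring feature is used instead (logged).
    ``selection_frequency`` counts, per feature, the training folds in which
    it was selected.
    """
    counts, labels = data.counts, data.labels
    per_class = min(int(labels.sum()), int((labels == 0).sum()))
    if per_class < n_folds:
        raise ValueError("need at least n_folds samples per class")
    master = np.random.default_rng(rng)
    fs_params = fs_params or {}

    aucs, ppvs, npvs = [], [], []
    sel_freq = np.zeros(data.n_features, int)
    for _ in range(n_repeats):
        fold_seed = int(master.integers(2**31 - 1))
        cv = StratifiedKFold(n_folds, shuffle=True, random_state=fold_seed)
        for train_idx, test_idx in cv.split(counts.T, labels):
            sub = LabeledCountMatrix(counts[:, train_idx], labels[train_idx])
            res = selectors.select_features(
                fs_method, sub, alpha=alpha, bonferroni=bonferroni,
                rng=np.random.default_rng(master.integers(2**31 - 1)), **fs_params)
            mask = res.selected.copy()
            if not mask.any():
                mask[res.top_feature()] = True
                log.info("empty selection in a fold; falling back to the top feature")
            sel_freq += mask
            tr_X, te_X = _transform(counts[np.ix_(mask, train_idx)],
                                    counts[np.ix_(mask, test_idx)])
            score, pred = _fit_score(classifier, tr_X, labels[train_idx], te_X,
                                     seed=int(master.integers(2**31 - 1)))
            aucs.append(auc(score, labels[test_idx]))
            p, n = ppv_npv(pred, labels[test_idx])
            ppvs.append(p)
            npvs.append(n)

    return ClassifierReport(
        dataset_id=dataset_id, fs_method=fs_method, classifier=classifier,
        auc=float(np.nanmean(aucs)), ppv=float(np.nanmean(ppvs)),
        npv=float(np.nanmean(npvs)), n_repeats=n_repeats, n_folds=n_folds,
        selection_frequency=sel_freq,
    )
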