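"""The non-NB feature selectors and the uniform selection front end.

Four selector families live here — the two-sided Wilcoxon rank-sum filter,
L1-penalised logistic regression with cross-validated penalty, a binary
particle-swarm wrapper scored by a decision tree (PSODT), and random-forest
permutation importance — plus :func:`select_features`, which dispatches any
selector id (including the three NB test pipelines) and returns a uniform
:class:`FSResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from . import nbmethods
from .simdata import LabeledCountMatrix

__all__ = [
    "FSResult",
    "rank_sum_select",
    "lasso_select",
    "psodt_select",
    "rf_select",
    "select_features",
    "SELECTOR_IDS",
]

SELECTOR_IDS = ("bayseq", "deseq", "edger", "ranksum", "lasso", "psodt", "rf")

#: largest per-group size for which the rank-sum test enumerates exactly
_EXACT_MAX_N = 8


@dataclass
class FSResult:
    """Per-feature scores plus the selected set and its decision rule.

    ``scores`` are p-values for the statistical selectors (lower is better),
    |coefficient|, swarm score or importance otherwise (higher is better);
    ``higher_is_better`` records the direction so downstream fallbacks can
    rank features.
    """

    method_tag: str
    scores: np.ndarray
    selected: np.ndarray
    rule: str
    higher_is_better: bool = False
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.selected = np.asarray(self.selected, bool)
        if self.scores.shape != self.selected.shape:
            raise ValueError("scores and selected must have equal length")
        if not self.rule:
            raise ValueError("rule must be populated")

    def top_feature(self) -> int:
        """Index of the best-scoring feature (fallback when nothing passes)."""
        return int(np.argmax(self.scores) if self.higher_is_better
                   else np.argmin(self.scores))

    def to_frame(self, feature_ids=None):
        import pandas as pd

        n = len(self.scores)
        ids = list(feature_ids) if feature_ids is not None else [f"f{i:04d}" for i in range(n)]
        return pd.DataFrame({
            "feature_id": ids, "score": self.scores, "selected": self.selected,
            "method_tag": self.method_tag, "rule": self.rule,
        })


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _exact_rank_sum_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by enumeration of all group
    assignments of the pooled midranks (handles ties)."""
    pooled = np.concatenate([case, ctrl])
    ranks = stats.rankdata(pooled)
    n1, n = len(case), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / comb(n, n1)


def rank_sum_select(
    counts: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> FSResult:
    """Two-sided Wilcoxon rank-sum test per feature.

    Groups of at most 8 per side are tested by exact enumeration over all
    rank assignments (midranks for ties); larger groups use the tie-corrected
    normal approximation with continuity correction.  A feature constant
    across all samples gets p = 1.
    """
    counts = np.asarray(counts)
    groups = np.asarray(groups).astype(int)
    case = counts[:, groups == 1]
    ctrl = counts[:, groups == 0]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("rank-sum test needs >=2 samples per group")
    constant = np.ptp(counts, axis=1) == 0

    if max(case.shape[1], ctrl.shape[1]) <= _EXACT_MAX_N:
        p = np.array([_exact_rank_sum_p(c, k) for c, k in zip(case, ctrl)])
    else:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.mannwhitneyu(case, ctrl, axis=1, method="asymptotic").pvalue
    p = np.where(constant | ~np.isfinite(p), 1.0, p)

    threshold = alpha / counts.shape[0] if bonferroni else alpha
    return FSResult(
        method_tag="ranksum", scores=p, selected=p < threshold,
        rule=f"p<{threshold:g}", p_values=p,
    )


# ---------------------------------------------------------------------------
# lasso

def _log_standardise(counts: np.ndarray) -> np.ndarray:
    """log2(count + 1), per-feature standardised; samples in rows."""
    x = np.log2(np.asarray(counts, float) + 1.0).T
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def lasso_select(
    counts: np.ndarray,
    groups: np.ndarray,
    n_folds: int = 5,
    rng: np.random.Generator | int | None = None,
    C: float | None = None,
    one_se: bool = False,
    n_Cs: int = 25,
) -> FSResult:
    """L1-penalised logistic regression on log-transformed counts.

    The inverse penalty ``C`` is chosen by ``n_folds``-fold cross-validation
    minimising the binomial deviance (``one_se=True`` switches to the
    sparsest penalty within one standard error of the minimum); features with
    nonzero coefficients at the chosen penalty are selected.  Passing ``C``
    skips the CV and fits at that penalty.
    """
    y = np.asarray(groups).astype(int)
    X = _log_standardise(counts)
    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    if C is not None:
        model = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                                   random_state=seed)
        model.fit(X, y)
        coef = model.coef_.ravel()
        rule = f"nonzero coef at C={C:g}"
    else:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        Cs = np.logspace(-3, 2, n_Cs)
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=Cs, cv=cv,
            scoring="neg_log_loss", refit=True, random_state=seed)
        model.fit(X, y)
        best_C = float(model.C_[0])
        if one_se:
            scores = model.scores_[1]  # (folds, Cs), neg log-loss
            mean, se = scores.mean(axis=0), scores.std(axis=0, ddof=1) / np.sqrt(n_folds)
            best_idx = int(np.argmax(mean))
            ok = mean >= mean[best_idx] - se[best_idx]
            best_C = float(Cs[np.flatnonzero(ok)[0]])  # smallest C = sparsest
            model = LogisticRegression(penalty="l1", C=best_C, solver="liblinear",
                                       random_state=seed).fit(X, y)
        coef = model.coef_.ravel()
        rule = f"nonzero coef at CV-chosen C={best_C:g}"
    selected = np.abs(coef) > 1e-8
    if not selected.any():
        warnings.warn("lasso path fully shrunk; empty selection", stacklevel=2)
    return FSResult(method_tag="lasso", scores=np.abs(coef), selected=selected,
                    rule=rule, higher_is_better=True)


# ---------------------------------------------------------------------------
# PSODT: binary particle swarm + decision tree

def _dt_fitness(X: np.ndarray, y: np.ndarray, mask: np.ndarray, seed: int) -> float:
    if not mask.any():
        return 0.0
    tree = DecisionTreeClassifier(random_state=seed)
    cv = StratifiedKFold(3, shuffle=True, random_state=seed)
    return float(cross_val_score(tree, X[:, mask], y, cv=cv).mean())


def psodt_select(
    counts: np.ndarray,
    groups: np.ndarray,
    swarm_size: int = 50,
    n_iters: int = 100,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 3,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
    restart_consensus: str = "all",
) -> FSResult:
    """Binary particle-swarm search over feature subsets, scored by a
    decision tree under internal stratified 3-fold cross-validation.

    Per iteration, every feature contained in the position of a particle
    whose personal best coincides with the current global best (the same
    subset) earns one score increment; the tally is returned as the score.
    Selection uses the subset the swarm actually converged to: a feature is
    selected when it belongs to the final global-best subset of every
    independent restart (``restart_consensus="all"``, the default) or of at
    least half of them (``"half"``).  Requiring consensus across restarts
    keeps the selected fraction small, mirroring how unstable single-run
    swarm subsets are.
    """
    y = np.asarray(groups).astype(int)
    X = _log_standardise(counts)
    n_features = X.shape[1]
    if min((y == 0).sum(), (y == 1).sum()) < 4:
        raise ValueError("PSODT needs >=4 samples per group")
    master = np.random.default_rng(rng)
    total_scores = np.zeros(n_features)
    positive_runs = np.zeros(n_features, int)

    for _ in range(max(n_restarts, 1)):
        run = np.random.default_rng(master.integers(2**31 - 1))
        seed = int(run.integers(2**31 - 1))
        pos = run.random((swarm_size, n_features)) < 0.5
        vel = run.uniform(-1, 1, (swarm_size, n_features))
        fitness = np.array([_dt_fitness(X, y, m, seed) for m in pos])
        pbest, pbest_fit = pos.copy(), fitness.copy()
        scores = np.zeros(n_features)
        for _ in range(n_iters):
            g = int(np.argmax(pbest_fit))
            gbest = pbest[g]
            r1 = run.random((swarm_size, n_features))
            r2 = run.random((swarm_size, n_features))
            vel = (inertia * vel
                   + cognitive * r1 * (pbest.astype(float) - pos)
                   + social * r2 * (gbest.astype(float)[None, :] - pos))
            pos = run.random((swarm_size, n_features)) < 1.0 / (1.0 + np.exp(-vel))
            fitness = np.array([_dt_fitness(X, y, m, seed) for m in pos])
            improved = fitness > pbest_fit
            pbest[improved] = pos[improved]
            pbest_fit[improved] = fitness[improved]
            # particles whose personal best is the reigning global-best subset
            gbest = pbest[int(np.argmax(pbest_fit))]
            at_best = np.all(pbest == gbest[None, :], axis=1)
            scores += pos[at_best].sum(axis=0)
        total_scores += scores
        if n_iters > 0:
            positive_runs += pbest[int(np.argmax(pbest_fit))].astype(int)

    n_runs = max(n_restarts, 1)
    need = n_runs if restart_consensus == "all" else int(np.ceil(n_runs / 2))
    selected = positive_runs >= need
    return FSResult(method_tag="psodt", scores=total_scores, selected=selected,
                    rule=f"in final gbest of >= {need}/{n_runs} restarts",
                    higher_is_better=True)


# ---------------------------------------------------------------------------
# random forest

def _oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag permutation importance (mean decrease in accuracy).

    Per tree, the accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature among those samples; only features
    the tree actually splits on can change its predictions, so the decrease
    is zero for the rest.  Returns the mean and standard deviation of the
    per-tree decreases over all trees.
    """
    n_samples, n_features = X.shape
    n_trees = len(forest.estimators_)
    dec_sum = np.zeros(n_features)
    dec_sq = np.zeros(n_features)
    for tree, boot_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n_samples), boot_idx)
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        used = np.unique(tree.tree_.feature)
        for j in used[used >= 0]:
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(len(oob)), j]
            drop = base - np.mean(tree.predict(X_perm) == y_oob)
            dec_sum[j] += drop
            dec_sq[j] += drop * drop
    mean = dec_sum / n_trees
    var = np.maximum(dec_sq / n_trees - mean**2, 0.0)
    return mean, np.sqrt(var)


def rf_select(
    counts: np.ndarray,
    groups: np.ndarray,
    n_trees: int = 500,
    mtry: int | None = None,
    rng: np.random.Generator | int | None = None,
    z_threshold: float = 2.0,
) -> FSResult:
    """Random forest with out-of-bag permutation importance.

    ``mtry`` (features tried per split) defaults to floor(sqrt(n_features)).
    Each feature's importance is its mean decrease in out-of-bag accuracy
    when permuted, scaled by its standard error over trees; features with
    scaled importance above ``z_threshold`` are selected.
    """
    y = np.asarray(groups).astype(int)
    X = np.asarray(counts, float).T
    n_features = X.shape[1]
    if mtry is None:
        mtry = max(int(np.sqrt(n_features)), 1)
    master = np.random.default_rng(rng)
    seed = int(master.integers(2**31 - 1))
    forest = RandomForestClassifier(n_estimators=n_trees, max_features=mtry,
                                    random_state=seed)
    forest.fit(X, y)
    imp, sd = _oob_permutation_importance(forest, X, y, master)
    se = sd / np.sqrt(n_trees)
    z = np.where(se > 0, imp / np.where(se > 0, se, 1.0), 0.0)
    return FSResult(method_tag="rf", scores=imp, selected=z > z_threshold,
                    rule=f"importance z>{z_threshold:g}", higher_is_better=True)


# ---------------------------------------------------------------------------
# dispatch

def select_features(
    method: str,
    data: LabeledCountMatrix,
    alpha: float = 0.05,
    bonferroni: bool = False,
    rng: np.random.Generator | int | None = None,
    **params,
) -> FSResult:
    """Run any selector by id and return a uniform :class:`FSResult`.

    The NB test pipelines (``bayseq``, ``deseq``, ``edger``) are thresholded
    at ``alpha`` (or ``alpha / n_features`` under Bonferroni), like
    ``ranksum``; ``lasso``, ``psodt`` and ``rf`` use their own rules.
    """
    counts, groups = data.counts, data.labels
    if method == "ranksum":
        return rank_sum_select(counts, groups, alpha=alpha, bonferroni=bonferroni, **params)
    if method == "lasso":
        return lasso_select(counts, groups, rng=rng, **params)
    if method == "psodt":
        return psodt_select(counts, groups, rng=rng, **params)
    if method == "rf":
        return rf_select(counts, groups, rng=rng, **params)
    if method in ("edger", "deseq", "bayseq"):
        if method == "edger":
            res = nbmethods.edger_like_test(counts, groups, **params)
        elif method == "deseq":
            res = nbmethods.deseq_like_test(counts, groups, **params)
        else:
            res = nbmethods.bayseq_like_posterior(
                counts, groups, rng=np.random.default_rng(rng), **params)
        threshold = alpha / counts.shape[0] if bonferroni else alpha
        return FSResult(method_tag=method, scores=res.p_values,
                        selected=res.p_values < threshold,
                        rule=f"p<{threshold:g}", p_values=res.p_values)
    raise ValueError(f"unknown selector {method!r}; choose from {SELECTOR_IDS}")
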