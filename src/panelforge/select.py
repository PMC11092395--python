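"""Tri-algorithm consensus feature selection.

Three independent selectors are run and their selections combined by
voting (a protein enters the candidate panel when chosen by at least two
algorithms):

* **Random forest** on the DEP set: stage 1 keeps proteins with scaled
  permutation importance (mean decrease accuracy, MDA) above a threshold
  on all samples; stage 2 runs repeated stratified 4:1 hold-out splits,
  re-selects MDA-passing features on each training set, and retains only
  iterations whose held-out accuracy and AUC are both exactly 1.  The
  per-protein score is its inclusion frequency across retained iterations.
* **LASSO** (L1-penalised logistic regression) on all quantified
  proteins: 10-fold cross-validated binomial deviance over a lambda path,
  one-standard-error rule, nonzero coefficients at the chosen lambda.
* **SVM forward search**: proteins ranked per sampling iteration by
  absolute Welch t on the training split; linear-SVM classifiers grown
  over ranked prefixes; the minimum classifier is the smallest prefix
  size attaining the lowest mean held-out error, and proteins are scored
  by inclusion frequency across iterations.

All selectors operate on per-protein z-scored abundances and derive all
randomness from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .differential import _welch_vectorized
from .simulate import GROUP_A, GROUP_B

__all__ = [
    "FeatureSet",
    "RFConfig",
    "ConsensusPanel",
    "zscore",
    "scaled_mda",
    "select_rf",
    "select_lasso",
    "select_svm",
    "consensus",
]


@dataclass
class FeatureSet:
    """One algorithm's ranked selection."""

    algorithm: str
    members: pd.DataFrame  # columns: protein, score
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return self.members["protein"].tolist()

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest selector parameters.

    ``mda_threshold`` is on the scaled importance (mean per-tree accuracy
    decrease divided by its standard error); ``retain`` requires held-out
    accuracy and AUC of exactly 1.
    """

    mda_threshold: float = 3.0
    n_trees: int = 1000
    n_iterations: int = 50
    split_ratio: float = 0.8
    frequency_cutoff: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.n_trees < 1 or self.n_iterations < 1:
            raise ValueError("n_trees and n_iterations must be positive")
        if not np.isfinite(self.mda_threshold) and self.mda_threshold < 0:
            raise ValueError("mda_threshold must be finite or +inf")


@dataclass
class ConsensusPanel:
    """Proteins selected by >= min_votes algorithms, with direction."""

    members: pd.DataFrame  # columns: protein, n_votes, direction
    min_votes: int = 2

    @property
    def proteins(self) -> list[str]:
        return self.members["protein"].tolist()

    def __len__(self) -> int:
        return len(self.members)


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each protein (row) across samples; constant rows map to 0."""
    values = matrix.to_numpy(dtype=float)
    mu = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((values - mu) / sd, index=matrix.index, columns=matrix.columns)


def _labels_array(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("need at least 2 samples per class")
    # positive class: lmCRC if present, else lexicographically last
    pos = GROUP_B if GROUP_B in classes else classes[-1]
    return (y == pos).astype(int)


def scaled_mda(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
    max_features: str | float = "sqrt",
) -> np.ndarray:
    """Scaled permutation importance (mean decrease accuracy).

    Classic forest recipe: each tree is grown on a bootstrap sample; for
    every feature, out-of-bag accuracy is compared with accuracy after
    permuting that feature among the out-of-bag rows.  The per-tree
    decreases are averaged and divided by their standard error across
    trees, giving a z-like score whose conventional selection threshold
    here is 3.
    """
    n, p = X.shape
    deltas = np.full((n_trees, p), np.nan)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=int(rng.integers(2**31 - 1)),
    )
    forest.fit(X, y)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    all_idx = np.arange(n)
    for t, (tree, boot) in enumerate(zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(all_idx, boot)
        if oob.size == 0:
            continue
        X_oob = X32[oob]
        y_oob = y[oob]
        n_oob = oob.size
        # one stacked predict per tree: block 0 unpermuted, block j+1 with
        # feature j permuted among the OOB rows
        stack = np.tile(X_oob, (p + 1, 1))
        for j in range(p):
            block = slice((j + 1) * n_oob, (j + 2) * n_oob)
            stack[block, j] = X_oob[rng.permutation(n_oob), j]
        pred = tree.predict(stack, check_input=False)
        acc = (pred.reshape(p + 1, n_oob) == y_oob).mean(axis=1)
        deltas[t] = acc[0] - acc[1:]
    valid = ~np.isnan(deltas[:, 0])
    n_valid = valid.sum()
    if n_valid == 0:
        return np.zeros(p)
    mean = np.nanmean(deltas, axis=0)
    sd = np.nanstd(deltas, axis=0, ddof=1) if n_valid > 1 else np.zeros(p)
    se = sd / np.sqrt(n_valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(se > 0, mean / se, 0.0)
    return score


def select_rf(
    matrix: pd.DataFrame, labels, config: RFConfig = RFConfig()
) -> FeatureSet:
    """Two-stage random-forest selection on the DEP submatrix.

    ``matrix`` is proteins x samples, already restricted to the DEP set
    (z-scoring is applied internally).  Returns the proteins whose
    inclusion frequency across retained perfect-performance hold-out
    iterations reaches ``config.frequency_cutoff``; raw frequencies for
    every stage-1 protein are kept in ``metadata['frequencies']``.
    """
    config.validate()
    y = _labels_array(labels)
    z = zscore(matrix)
    X = z.to_numpy(dtype=float).T
    proteins = np.asarray(z.index)
    rng = np.random.default_rng(config.seed)

    mda_all = scaled_mda(X, y, config.n_trees, rng)
    stage1 = np.flatnonzero(mda_all > config.mda_threshold)
    meta: dict[str, Any] = {
        "stage1_mda": pd.Series(mda_all, index=proteins),
        "stage1_proteins": proteins[stage1].tolist(),
        "retained_models": 0,
        "n_iterations": config.n_iterations,
        "redrawn_splits": 0,
        "diagnostic": "",
    }
    if stage1.size == 0:
        meta["diagnostic"] = "no protein passed the stage-1 MDA threshold"
        return FeatureSet("rf", pd.DataFrame(columns=["protein", "score"]), meta)

    Xs = X[:, stage1]
    counts = np.zeros(stage1.size)
    retained = 0
    splitter = StratifiedShuffleSplit(
        n_splits=config.n_iterations,
        train_size=config.split_ratio,
        random_state=int(rng.integers(2**31 - 1)),
    )
    for train, test in splitter.split(Xs, y):
        mda_tr = scaled_mda(Xs[train], y[train], config.n_trees, rng)
        feats = np.flatnonzero(mda_tr > config.mda_threshold)
        if feats.size == 0:
            continue
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=int(rng.integers(2**31 - 1))
        )
        forest.fit(Xs[train][:, feats], y[train])
        prob = forest.predict_proba(Xs[test][:, feats])[:, 1]
        acc = np.mean((prob > 0.5).astype(int) == y[test])
        auc = roc_auc_score(y[test], prob)
        if acc == 1.0 and auc == 1.0:
            retained += 1
            counts[feats] += 1

    meta["retained_models"] = retained
    if retained == 0:
        meta["diagnostic"] = "no hold-out iteration reached accuracy 1 and AUC 1"
        meta["frequencies"] = pd.Series(0.0, index=proteins[stage1])
        return FeatureSet("rf", pd.DataFrame(columns=["protein", "score"]), meta)

    freq = counts / retained
    meta["frequencies"] = pd.Series(freq, index=proteins[stage1])
    keep = freq >= config.frequency_cutoff
    order = np.argsort(-freq[keep], kind="stable")
    members = pd.DataFrame(
        {
            "protein": proteins[stage1][keep][order],
            "score": freq[keep][order],
        }
    )
    return FeatureSet("rf", members, meta)


def _lambda_path(
    X: np.ndarray, y: np.ndarray, n_lambda: int, min_ratio: float
) -> np.ndarray:
    # glmnet-style: lambda_max is the smallest penalty zeroing every
    # coefficient, from the null-model gradient max |X^T (y - ybar)| / n
    n = X.shape[0]
    resid = y - y.mean()
    lam_max = np.max(np.abs(X.T @ resid)) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn minimises sum(logloss) + (1/C)||beta||_1; the glmnet
    # objective mean(logloss) + lam*||beta||_1 maps to C = 1/(n*lam)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (X.shape[0] * lam), solver="liblinear",
        max_iter=200, random_state=0, tol=1e-5,
    )
    model.fit(X, y)
    return model


def select_lasso(
    matrix: pd.DataFrame,
    labels,
    n_folds: int = 10,
    n_lambda: int = 80,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> FeatureSet:
    """L1-penalised logistic selection with the one-standard-error rule.

    ``matrix`` is proteins x samples over all quantified proteins (missing
    cells must be imputed upstream).  The cross-validation criterion is the
    mean held-out binomial deviance; the chosen lambda is the largest whose
    mean deviance is within one standard error of the minimum, and the
    feature set is the proteins with nonzero coefficients when refit on all
    samples at that lambda.
    """
    y = _labels_array(labels)
    z = zscore(matrix)
    X = z.to_numpy(dtype=float).T
    proteins = np.asarray(z.index)

    lambdas = _lambda_path(X, y, n_lambda, lambda_min_ratio)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    dev = np.zeros((n_folds, lambdas.size))
    for f, (train, test) in enumerate(cv.split(X, y)):
        for i, lam in enumerate(lambdas):
            model = _l1_logistic(X[train], y[train], lam)
            prob = model.predict_proba(X[test])[:, 1]
            dev[f, i] = 2.0 * log_loss(y[test], prob, labels=[0, 1])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))
    within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
    i_1se = int(np.flatnonzero(within)[0])  # lambdas descend: first = largest

    final = _l1_logistic(X, y, lambdas[i_1se])
    coef = final.coef_.ravel()
    nz = np.flatnonzero(coef != 0)
    order = np.argsort(-np.abs(coef[nz]), kind="stable")
    members = pd.DataFrame(
        {"protein": proteins[nz][order], "score": np.abs(coef[nz][order])}
    )
    meta = {
        "lambda_min": float(lambdas[i_min]),
        "lambda_1se": float(lambdas[i_1se]),
        "lambdas": lambdas,
        "cv_mean_deviance": mean_dev,
        "cv_se_deviance": se_dev,
        "coefficients": pd.Series(coef, index=proteins),
        "n_folds": n_folds,
    }
    return FeatureSet("lasso", members, meta)


def select_svm(
    matrix: pd.DataFrame,
    labels,
    n_iterations: int = 6,
    max_panel: int = 50,
    train_size: float = 0.8,
    seed: int = 0,
    rank_fn=None,
) -> FeatureSet:
    """Forward-growing linear-SVM minimum classifier.

    Per sampling iteration, proteins are ranked on the training split
    (default: absolute Welch t; pluggable via ``rank_fn(X_train, y_train)
    -> scores``), and a linear SVM is evaluated on the held-out split for
    every ranked prefix up to ``max_panel``.  The minimum classifier is
    the smallest prefix size whose mean held-out error across iterations
    is lowest; the returned members are the ``k*`` proteins with highest
    inclusion frequency among the per-iteration top-``k*`` sets.
    """
    y = _labels_array(labels)
    z = zscore(matrix)
    X = z.to_numpy(dtype=float).T
    proteins = np.asarray(z.index)
    p = proteins.size
    kmax = min(max_panel, p)

    if rank_fn is None:

        def rank_fn(X_tr, y_tr):
            t, _, _ = _welch_vectorized(X_tr[y_tr == 1].T, X_tr[y_tr == 0].T)
            t = np.abs(t)
            return np.where(np.isfinite(t), t, 0.0)  # constant features sink

    splitter = StratifiedShuffleSplit(
        n_splits=n_iterations, train_size=train_size, random_state=int(seed)
    )
    errors = np.zeros((n_iterations, kmax))
    rankings = []
    for it, (train, test) in enumerate(splitter.split(X, y)):
        scores = rank_fn(X[train], y[train])
        order = np.argsort(-scores, kind="stable")
        rankings.append(order)
        for k in range(1, kmax + 1):
            clf = SVC(kernel="linear")
            clf.fit(X[train][:, order[:k]], y[train])
            errors[it, k - 1] = np.mean(clf.predict(X[test][:, order[:k]]) != y[test])

    mean_err = errors.mean(axis=0)
    k_star = int(np.flatnonzero(mean_err == mean_err.min())[0]) + 1
    counts = np.zeros(p)
    for order in rankings:
        counts[order[:k_star]] += 1
    freq = counts / n_iterations
    order_idx = sorted(range(p), key=lambda j: (-freq[j], j))[:k_star]
    members = pd.DataFrame(
        {"protein": proteins[order_idx], "score": freq[order_idx]}
    )
    members = members[members.score > 0].reset_index(drop=True)
    meta = {
        "cv_error_by_size": mean_err,
        "k_star": k_star,
        "min_cv_error": float(mean_err.min()),
        "inclusion_frequency": pd.Series(freq, index=proteins),
        "n_iterations": n_iterations,
    }
    return FeatureSet("svm", members, meta)


def consensus(
    sets: list[FeatureSet],
    min_votes: int = 2,
    dep_table: pd.DataFrame | None = None,
) -> ConsensusPanel:
    """Vote across algorithm feature sets.

    A protein enters the panel when it appears in at least ``min_votes``
    of the input sets.  Direction (which group the protein is up in) is
    taken from the sign of ``log2_fold_change`` in ``dep_table`` when
    provided.  Output order: votes descending, then protein id — invariant
    to the order of the input sets.
    """
    if len(sets) < 1:
        raise ValueError("need at least one feature set")
    votes: dict[str, int] = {}
    for fs in sets:
        for prot in set(fs.proteins):
            votes[prot] = votes.get(prot, 0) + 1
    kept = sorted(
        (p for p, v in votes.items() if v >= min_votes),
        key=lambda p: (-votes[p], p),
    )
    directions = []
    for prot in kept:
        if dep_table is not None and prot in dep_table.index:
            lfc = dep_table.loc[prot, "log2_fold_change"]
            directions.append(
                "" if not np.isfinite(lfc) or lfc == 0
                else (f"up_in_{GROUP_B}" if lfc > 0 else f"up_in_{GROUP_A}")
            )
        else:
            directions.append("")
    members = pd.DataFrame(
        {"protein": kept, "n_votes": [votes[p] for p in kept], "direction": directions}
    )
    return ConsensusPanel(members=members, min_votes=min_votes)
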