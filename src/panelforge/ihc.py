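"""Validation-arm statistics for IHC marker panels.

H-score computation (weighted percentages of tumour cells at weak,
moderate and strong staining intensity, range 0-300), per-marker ROC
analysis with DeLong confidence intervals, DeLong comparison of
correlated ROC curves, Fisher's exact positivity tests, logistic
multimarker combination, Wilcoxon rank-sum group comparison and
correlation-based 2-cluster sample grouping.

The DeLong machinery is implemented from the structural-components
estimator: AUC as the Mann-Whitney statistic with ties at 1/2, the
variance from the empirical covariance of per-case placement values, and
the paired comparison from the shared components of two markers scored on
the same patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ROCSummary",
    "DeLongComparison",
    "ClusterResult",
    "compute_hscore",
    "add_hscore",
    "auc_delong",
    "compare_auc_delong",
    "positivity_tests",
    "logistic_combination",
    "correlation_cluster",
    "rank_sum_test",
]


@dataclass
class ROCSummary:
    """One marker's ROC summary with a 95% DeLong interval."""

    marker: str
    auc: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float  # H0: AUC = 0.5
    direction: str  # group whose scores are higher
    raw_auc: float  # before any >= 0.5 orientation


@dataclass
class DeLongComparison:
    """Paired comparison of two correlated AUCs."""

    pair: tuple[str, str]
    auc_1: float
    auc_2: float
    auc_difference: float
    z_statistic: float
    p_value: float


def compute_hscore(pct_weak, pct_moderate, pct_strong):
    """H-score = weak% * 1 + moderate% * 2 + strong% * 3, in [0, 300]."""
    w = np.asarray(pct_weak, dtype=float)
    m = np.asarray(pct_moderate, dtype=float)
    s = np.asarray(pct_strong, dtype=float)
    if (w < 0).any() or (m < 0).any() or (s < 0).any():
        raise ValueError("staining percentages must be nonnegative")
    if (w + m + s > 100 + 1e-9).any():
        raise ValueError("staining percentages must sum to at most 100")
    h = w + 2.0 * m + 3.0 * s
    return float(h) if h.ndim == 0 else h


def add_hscore(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a staining table with the derived hscore column."""
    out = table.copy()
    out["hscore"] = compute_hscore(
        out["pct_weak"], out["pct_moderate"], out["pct_strong"]
    )
    return out


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Midrank AUC and DeLong structural components.

    V10[i] = fraction of negatives the i-th positive outranks (ties 1/2);
    V01[j] analogous for negatives.  AUC = mean(V10) = 1 - mean(V01).
    """
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    pos_ranks = ranks[:m]
    neg_ranks = ranks[m:]
    v10 = (pos_ranks - stats.rankdata(pos)) / n
    v01 = 1.0 - (neg_ranks - stats.rankdata(neg)) / m
    # single-division Mann-Whitney form: exact agreement with pair counting
    auc = (pos_ranks.sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


def _split_scores(scores, labels, positive_label=None) -> tuple[np.ndarray, np.ndarray, str, str]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    pos_label = positive_label if positive_label is not None else classes[-1]
    neg_label = classes[0] if pos_label == classes[-1] else classes[-1]
    pos = scores[labels == pos_label]
    neg = scores[labels == neg_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one score per class")
    return pos, neg, str(pos_label), str(neg_label)


def auc_delong(
    scores,
    labels,
    marker: str = "",
    positive_label=None,
    orient: bool = True,
) -> ROCSummary:
    """AUC with DeLong variance, 95% CI and p versus 0.5.

    The AUC is the Mann-Whitney U / (n1*n2) with ties counted 1/2; its
    variance comes from the structural components var(V10)/m + var(V01)/n.
    With ``orient=True`` the reported AUC is flipped to >= 0.5 (the raw
    value and scoring direction are retained).  The CI is the normal
    approximation truncated to [0, 1]; perfect separation yields a
    degenerate interval at the AUC.
    """
    pos, neg, pos_label, neg_label = _split_scores(scores, labels, positive_label)
    auc, v10, v01 = _placements(pos, neg)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    se = float(np.sqrt(var))

    raw = auc
    direction = pos_label if raw >= 0.5 else neg_label
    if orient and raw < 0.5:
        auc = 1.0 - raw
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        ci_low = max(0.0, auc - 1.959963984540054 * se)
        ci_high = min(1.0, auc + 1.959963984540054 * se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
        ci_low = ci_high = auc
    return ROCSummary(
        marker=marker,
        auc=float(auc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        se=se,
        p_value=p,
        direction=direction,
        raw_auc=float(raw),
    )


def compare_auc_delong(
    scores_1, scores_2, labels, pair: tuple[str, str] = ("marker_1", "marker_2")
) -> DeLongComparison:
    """DeLong test for two correlated ROC curves on the same patients.

    z = (AUC1 - AUC2) / sqrt(var1 + var2 - 2*cov), with the covariance
    estimated from the shared structural components; two-sided normal p.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("paired score vectors must cover the same patients")
    labels = np.asarray(labels)
    pos1, neg1, *_ = _split_scores(s1, labels)
    pos2, neg2, *_ = _split_scores(s2, labels)
    a1, v10_1, v01_1 = _placements(pos1, neg1)
    a2, v10_2, v01_2 = _placements(pos2, neg2)
    m, n = pos1.size, neg1.size
    var1 = var2 = cov = 0.0
    if m > 1:
        var1 += np.var(v10_1, ddof=1) / m
        var2 += np.var(v10_2, ddof=1) / m
        cov += np.cov(v10_1, v10_2, ddof=1)[0, 1] / m
    if n > 1:
        var1 += np.var(v01_1, ddof=1) / n
        var2 += np.var(v01_2, ddof=1) / n
        cov += np.cov(v01_1, v01_2, ddof=1)[0, 1] / n
    denom = var1 + var2 - 2.0 * cov
    diff = a1 - a2
    if denom <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(denom)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(
        pair=pair,
        auc_1=float(a1),
        auc_2=float(a2),
        auc_difference=float(diff),
        z_statistic=float(z),
        p_value=p,
    )


def positivity_tests(counts) -> dict:
    """Fisher's exact test on a 2x2 positive/negative x group table.

    ``counts`` is [[pos_a, pos_b], [neg_a, neg_b]].  Returns the
    two-sided hypergeometric p and per-group positivity percentages.
    Tables with a zero margin carry no information about association and
    report p = 1 with a flag.
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    zero_margin = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if zero_margin:
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    col_tot = table.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pct = np.where(col_tot > 0, 100.0 * table[0] / col_tot, np.nan)
    return {
        "fisher_p": p,
        "positivity_pct": {"group_a": float(pct[0]), "group_b": float(pct[1])},
        "zero_margin": bool(zero_margin),
    }


def logistic_combination(
    hscores: pd.DataFrame, labels, positive_label=None
) -> tuple[pd.Series, ROCSummary, bool]:
    """Multimarker logistic combination of H-scores.

    Fits a maximum-likelihood logistic model of group on the marker
    H-scores (patients x markers) and summarises the in-sample ROC of the
    linear predictor.  Complete or quasi-complete separation is detected;
    the coefficients are then reported as non-finite while the ROC is
    still computed from a separating direction (a lightly ridge-penalised
    fit), which leaves the AUC well-defined.

    Returns ``(coefficients, roc_summary, separated)``.
    """
    import statsmodels.api as sm

    X = hscores.to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 2 patients per class")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant-column marker in design")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two groups")
    pos_label = positive_label if positive_label is not None else classes[-1]
    y = (labels == pos_label).astype(float)

    design = sm.add_constant(X)
    names = ["const"] + list(hscores.columns)
    separated = False
    params = None
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = fit.params
        # quasi-separation shows up as exploding coefficients / zero deviance
        if not np.all(np.isfinite(params)) or np.abs(params[1:]).max() > 1e3:
            separated = True
    except Exception:
        separated = True

    if separated or params is None:
        from sklearn.linear_model import LogisticRegression

        ridge = LogisticRegression(l1_ratio=0.0, C=1e4, max_iter=5000)
        ridge.fit(X, y)
        direction = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
        scores = design @ direction
        coef = pd.Series(np.full(len(names), np.nan), index=names)
        separated = True
    else:
        scores = design @ params
        coef = pd.Series(params, index=names)

    roc = auc_delong(scores, y, marker="+".join(hscores.columns), positive_label=1)
    return coef, roc, separated


@dataclass
class ClusterResult:
    """2-cluster correlation clustering of samples."""

    assignments: pd.Series
    correlation: pd.DataFrame  # reordered by dendrogram leaves
    agreement: float | None  # best label agreement over cluster relabelling


def correlation_cluster(
    samples: pd.DataFrame, labels=None
) -> ClusterResult:
    """Average-linkage clustering of samples on correlation distance.

    ``samples`` has one row per sample/patient and one column per feature
    (protein or marker H-score).  Pairwise Pearson correlation r gives the
    distance 1 - r; the dendrogram is cut at 2 clusters.  When group
    labels are supplied, the agreement is the best achievable fraction of
    matching assignments over the two cluster labelings.
    """
    if samples.shape[0] < 2 or samples.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    values = samples.to_numpy(dtype=float)
    if (values.std(axis=1) == 0).any():
        raise ValueError("zero-variance sample vector; correlation undefined")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # symmetrise away float noise
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=2, criterion="maxclust")
    order = leaves_list(Z)
    corr_df = pd.DataFrame(corr, index=samples.index, columns=samples.index)
    corr_df = corr_df.iloc[order, order]
    agreement = None
    if labels is not None:
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size == 2:
            match1 = np.mean((assign == 1) == (labels == classes[0]))
            agreement = float(max(match1, 1.0 - match1))
    return ClusterResult(
        assignments=pd.Series(assign, index=samples.index, name="cluster"),
        correlation=corr_df,
        agreement=agreement,
    )


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for small tie-free samples (both groups <= 20),
    otherwise the normal approximation with tie correction.  Returns
    ``(U statistic for x, two-sided p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
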