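"""Differential-expression screen between the PAIM and lmCRC groups.

Per protein: an unpaired two-sided Welch's t test on the abundance ratios
(pairwise-complete, i.e. missing values dropped per protein), Benjamini-
Hochberg adjustment across the testable proteins, and a fold change
defined as mean(lmCRC ratios) / mean(PAIM ratios).  A protein is called
differentially expressed (DEP) when the adjusted p is strictly below
``alpha`` AND |log2FC| strictly exceeds ``lfc``.

Sample embedding for cluster visualisation delegates to UMAP on the DEP
submatrix (z-scored per protein), seeded for determinism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GROUP_A, GROUP_B

__all__ = ["welch_test", "bh_adjust", "call_deps", "embed_umap"]


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test for two independent samples.

    Missing values are dropped.  Returns ``(t, df, p)`` with t oriented as
    mean(x) - mean(y) and df from the Welch-Satterthwaite approximation.
    If either group has fewer than 2 present values, or both groups are
    exactly constant (zero pooled variance), the protein is untestable and
    ``(nan, nan, nan)`` is returned rather than a silent p of 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return (np.nan, np.nan, np.nan)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return (np.nan, np.nan, np.nan)
    res = stats.ttest_ind(x, y, equal_var=False)
    return (float(res.statistic), float(res.df), float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    NaN entries (untestable hypotheses) are excluded from the family size
    m and returned as NaN.  Values are monotone-enforced and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.any():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def _group_columns(sheet: pd.DataFrame) -> tuple[list[str], list[str]]:
    study = sheet[sheet.role == "study"]
    a = study.loc[study.group == GROUP_A, "sample_id"].tolist()
    b = study.loc[study.group == GROUP_B, "sample_id"].tolist()
    return a, b


def _welch_vectorized(
    xa: np.ndarray, xb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test with NaN-aware moments (proteins x samples)."""
    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(xa, axis=1)
        mb = np.nanmean(xb, axis=1)
        va = np.nanvar(xa, axis=1, ddof=1)
        vb = np.nanvar(xb, axis=1, ddof=1)
        sa, sb = va / na, vb / nb
        se2 = sa + sb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    bad = (na < 2) | (nb < 2) | (se2 == 0) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    p = np.where(bad, np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    return t, df, p


def call_deps(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha: float = 0.05,
    lfc: float = 0.25,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Screen DEPs between the two study groups.

    Parameters
    ----------
    matrix : DataFrame, proteins x samples
        Abundance ratios (outlier-imputed; missing cells allowed and
        handled pairwise-complete).
    sheet : DataFrame
        Sample sheet; only rows with ``role == 'study'`` are used.
    alpha, lfc : float
        Strict thresholds: DEP iff adjusted p < alpha and |log2FC| > lfc.
    log_scale : bool
        If True, run the Welch test on log2 ratios instead of raw ratios.
        Fold change is always computed from the raw ratio means.

    Returns
    -------
    DataFrame indexed by protein: ``t, df, p, adj_p, fold_change,
    log2_fold_change, is_dep, direction`` (direction: which group the
    protein is up in, from the fold-change sign).
    """
    cols_a, cols_b = _group_columns(sheet)
    if not cols_a or not cols_b:
        raise ValueError("both study groups must be present in the sample sheet")
    xa = matrix[cols_a].to_numpy(dtype=float)
    xb = matrix[cols_b].to_numpy(dtype=float)

    if log_scale:
        t, df, p = _welch_vectorized(np.log2(xa), np.log2(xb))
    else:
        t, df, p = _welch_vectorized(xa, xb)
    adj = bh_adjust(p)

    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.nanmean(xb, axis=1) / np.nanmean(xa, axis=1)  # lmCRC / PAIM
        log2fc = np.log2(fc)
    is_dep = (adj < alpha) & (np.abs(log2fc) > lfc)
    is_dep = np.where(np.isnan(adj) | np.isnan(log2fc), False, is_dep)
    direction = np.where(
        np.isnan(log2fc) | (log2fc == 0),
        "",
        np.where(log2fc > 0, f"up_in_{GROUP_B}", f"up_in_{GROUP_A}"),
    )
    return pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p": p,
            "adj_p": adj,
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "is_dep": is_dep.astype(bool),
            "direction": direction,
        },
        index=matrix.index,
    )


def embed_umap(
    dep_matrix: pd.DataFrame, seed: int = 0, n_neighbors: int = 15
) -> pd.DataFrame:
    """2-D UMAP embedding of samples from the DEP submatrix.

    Rows are proteins (the DEP set), columns samples; each protein is
    z-scored across samples before embedding.  Deterministic for a fixed
    seed (single-threaded exact nearest neighbours).
    """
    if dep_matrix.shape[0] == 0:
        raise ValueError("DEP set is empty; nothing to embed")
    n_samples = dep_matrix.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples to embed")
    import umap  # deferred: slow import

    values = dep_matrix.to_numpy(dtype=float)
    mu = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    z = np.nan_to_num(z, nan=0.0)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n_samples - 1),
        random_state=int(seed),
        force_approximation_algorithm=False,
    )
    coords = reducer.fit_transform(z.T)
    return pd.DataFrame(coords, index=dep_matrix.columns, columns=["umap1", "umap2"])
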