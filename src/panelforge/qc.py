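"""Quality control and imputation of the abundance-ratio matrix.

Two imputation rules are applied ahead of any analysis:

* Tukey's-fences outlier imputation: a single global upper cutoff
  ``Q3 + k*IQR`` (k = 2) over the pooled distribution of all present
  cells; every value above the fence is replaced by the fence value.
* Missing-value imputation with ``0.8 x`` the global minimum of the
  present values (applied to the study submatrix ahead of feature
  selection; the differential stage works on pairwise-complete values).

Reproducibility is summarised with coefficients of variation (CV):
per-protein CVs across the common pooled reference samples and per
technical-replicate pair, with a 20% pass threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FenceReport",
    "QCReport",
    "tukey_fence_impute",
    "impute_missing",
    "compute_cvs",
]

CV_PASS_THRESHOLD = 0.20


@dataclass
class FenceReport:
    """Outcome of the global Tukey's-fences outlier imputation."""

    fence_value: float
    q1: float
    q3: float
    k: float
    outlier_fraction: float
    n_replaced: int
    quartile_method: str = "linear"

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class QCReport:
    """CV-based reproducibility summary for pools and replicate pairs."""

    pool_cvs: pd.Series
    replicate_pair_cvs: dict[str, pd.Series]
    missing_fraction: float
    pool_cv_median: float
    pair_cv_medians: dict[str, float]
    cv_threshold: float = CV_PASS_THRESHOLD
    fence: FenceReport | None = None

    @property
    def pool_pass(self) -> bool:
        return bool(self.pool_cv_median < self.cv_threshold)

    @property
    def pair_pass(self) -> dict[str, bool]:
        return {k: bool(v < self.cv_threshold) for k, v in self.pair_cv_medians.items()}

    def to_json(self, path) -> None:
        payload = {
            "missing_fraction": self.missing_fraction,
            "pool_cv_median": self.pool_cv_median,
            "pool_pass": self.pool_pass,
            "pair_cv_medians": self.pair_cv_medians,
            "pair_pass": self.pair_pass,
            "cv_threshold": self.cv_threshold,
        }
        if self.fence is not None:
            payload["fence"] = {
                "fence_value": self.fence.fence_value,
                "q1": self.fence.q1,
                "q3": self.fence.q3,
                "k": self.fence.k,
                "outlier_fraction": self.fence.outlier_fraction,
                "n_replaced": self.fence.n_replaced,
                "quartile_method": self.fence.quartile_method,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _validate_matrix(matrix: pd.DataFrame) -> np.ndarray:
    if matrix.size == 0:
        raise ValueError("abundance matrix is empty")
    values = matrix.to_numpy(dtype=float)
    present = values[~np.isnan(values)]
    if present.size and (present <= 0).any():
        raise ValueError("abundance ratios must be strictly positive where present")
    return values


def tukey_fence_impute(
    matrix: pd.DataFrame, k: float = 2.0
) -> tuple[pd.DataFrame, FenceReport]:
    """Impute high-tail outliers at a single global Tukey fence.

    The upper fence ``Q3 + k*IQR`` is computed once over the pooled
    distribution of every present cell in the matrix (linear-interpolation
    quartiles); all values above the fence are replaced by the fence value.
    Missing cells are untouched and no lower fence is enforced (ratios are
    bounded below by zero).

    Returns the imputed matrix and a :class:`FenceReport` recording the
    fence, quartiles and fraction of cells replaced.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    values = _validate_matrix(matrix)
    present = ~np.isnan(values)
    if present.sum() < 4:
        raise ValueError("need at least 4 present values to compute quartiles")
    q1, q3 = np.percentile(values[present], [25, 75])
    fence = q3 + k * (q3 - q1)
    above = present & (values > fence)
    out = values.copy()
    out[above] = fence
    report = FenceReport(
        fence_value=float(fence),
        q1=float(q1),
        q3=float(q3),
        k=float(k),
        outlier_fraction=float(above.sum() / present.sum()),
        n_replaced=int(above.sum()),
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), report


def impute_missing(matrix: pd.DataFrame, factor: float = 0.8) -> pd.DataFrame:
    """Replace every missing cell with ``factor x`` the global minimum.

    The minimum is taken over all present values of the whole matrix;
    present values are never altered.
    """
    values = _validate_matrix(matrix)
    present = ~np.isnan(values)
    if not present.any():
        raise ValueError("cannot impute an all-missing matrix")
    fill = factor * values[present].min()
    out = values.copy()
    out[~present] = fill
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_cvs(matrix: pd.DataFrame, sheet: pd.DataFrame) -> QCReport:
    """Per-protein CVs across pooled samples and per replicate pair.

    CV = sample SD (n-1 denominator) / mean, per protein across the pool
    columns, and per technical-replicate pair across its two columns
    (restricted to proteins present in both).  Medians are compared with
    the 20% reproducibility threshold.
    """
    pools = sheet.loc[sheet.role == "pool", "sample_id"].tolist()
    reps = sheet.loc[sheet.role == "replicate", ["sample_id", "replicate_of"]]
    if len(pools) < 2:
        raise ValueError("need at least 2 pool samples for pool CVs")
    if reps.empty:
        raise ValueError("need at least 1 replicate pair for replicate CVs")
    missing_cols = set(pools) | set(reps.sample_id) | set(reps.replicate_of)
    absent = missing_cols - set(matrix.columns)
    if absent:
        raise ValueError(f"annotated samples missing from matrix: {sorted(absent)}")

    pool_values = matrix[pools]
    pool_cvs = pool_values.std(axis=1, ddof=1) / pool_values.mean(axis=1)

    pair_cvs: dict[str, pd.Series] = {}
    for _, row in reps.iterrows():
        pair = matrix[[row.replicate_of, row.sample_id]].dropna()
        name = f"{row.replicate_of}|{row.sample_id}"
        pair_cvs[name] = pair.std(axis=1, ddof=1) / pair.mean(axis=1)

    missing_fraction = float(np.isnan(matrix.to_numpy(dtype=float)).mean())
    return QCReport(
        pool_cvs=pool_cvs,
        replicate_pair_cvs=pair_cvs,
        missing_fraction=missing_fraction,
        pool_cv_median=float(pool_cvs.median()),
        pair_cv_medians={k: float(v.median()) for k, v in pair_cvs.items()},
    )
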