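"""Reading and writing of the pipeline's tabular formats.

Abundance matrices travel as TSV (rows = proteins, header = sample ids),
sample sheets and H-score tables as CSV, reports and manifests as JSON.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sheet",
    "write_sheet",
    "read_hscores",
    "write_hscores",
    "sha256sum",
]


def read_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "protein"
    if matrix.index.duplicated().any():
        raise ValueError("duplicate protein ids in matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in matrix")
    return matrix


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "group", "batch", "role", "replicate_of"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    bad = sheet[(sheet.role == "replicate") != (sheet.replicate_of != "")]
    if not bad.empty:
        raise ValueError("replicate_of must be set exactly for role=replicate rows")
    if (sheet.loc[sheet.role == "pool", "group"] != "none").any():
        raise ValueError("pool samples must have group=none")
    return sheet


def write_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_hscores(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"patient_id", "group", "marker", "pct_weak", "pct_moderate", "pct_strong"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"H-score table is missing columns: {sorted(missing)}")
    return table


def write_hscores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def sha256sum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
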