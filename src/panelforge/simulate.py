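"""Synthetic data generation for the biomarker-panel pipeline.

Emulates the structure of a TMT ratio-to-pool proteomic study: two patient
groups (PAIM, primary lung adenocarcinoma with intestinal/mucinous
differentiation, vs lmCRC, lung metastasis of colorectal cancer) profiled in
16-plex batches with common pooled reference channels and technical
replicates, plus an immunohistochemistry (IHC) H-score table for a marker
panel scored on an independent cohort.

Abundances are ratios to the pooled reference channel, modelled as
log2-normal around 1: ``ratio = 2**(batch shift + group effect + noise)``.
A configurable set of "planted" proteins carries a true group effect; their
identities, injected missing cells and injected high-tail outlier cells are
recorded in a :class:`GroundTruth` object so downstream stages can be tested
for parameter recovery and error control without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

GROUP_A = "PAIM"
GROUP_B = "lmCRC"

__all__ = [
    "GROUP_A",
    "GROUP_B",
    "SimulationConfig",
    "GroundTruth",
    "simulate_abundance",
    "simulate_ihc",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the abundance-matrix generator.

    Defaults mirror the emulated study design: 22 vs 17 study samples in
    3 TMT batches with 3 common pools and 6 technical replicates (3 intra-
    and 3 inter-batch), ~7,871 quantified proteins, 5.7% missing cells and
    2.6% high-tail outlier cells.

    Parameters
    ----------
    n_group_a, n_group_b : int
        Study samples per group (PAIM / lmCRC).
    n_proteins : int
        Number of quantified proteins (matrix rows).
    n_batches : int
        TMT batches; study samples are spread across them round-robin.
    n_pools : int
        Common pooled samples, one per batch up to ``n_batches``.
    n_intra_replicates, n_inter_replicates : int
        Technical replicates re-measured in the same / a different batch.
    missing_rate, outlier_rate : float
        Fractions of matrix cells set missing / multiplied into the upper
        outlier tail (completely at random, disjoint cell sets).
    n_planted : int
        Number of proteins given a true between-group effect.
    effect_log2fc : float
        Absolute group effect on the log2 scale for planted proteins
        (must exceed 0.25 to be callable at the pipeline's default
        fold-change threshold).
    noise_sd : float
        Within-group biological + measurement SD on the log2 scale.
    batch_sd : float
        SD of per-protein, per-batch shifts on the log2 scale.
    tech_sd : float
        SD of technical-replicate noise on the log2 scale (~5% CV).
    pool_sd : float
        SD of pooled-sample noise around the per-protein global mean.
    seed : int
        Seed for every source of randomness in the generator.
    """

    n_group_a: int = 22
    n_group_b: int = 17
    n_proteins: int = 7871
    n_batches: int = 3
    n_pools: int = 3
    n_intra_replicates: int = 3
    n_inter_replicates: int = 3
    missing_rate: float = 0.057
    outlier_rate: float = 0.026
    n_planted: int = 105
    effect_log2fc: float = 0.6
    noise_sd: float = 0.25
    batch_sd: float = 0.1
    tech_sd: float = 0.05
    pool_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "n_proteins": self.n_proteins,
            "n_batches": self.n_batches,
            "n_pools": self.n_pools,
            "n_intra_replicates": self.n_intra_replicates,
            "n_inter_replicates": self.n_inter_replicates,
            "n_planted": self.n_planted,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        for name in ("missing_rate", "outlier_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate!r}")
        if self.n_planted > self.n_proteins:
            raise ValueError("n_planted cannot exceed n_proteins")
        for name in ("noise_sd", "batch_sd", "tech_sd", "pool_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """Record of everything the generator planted, for recovery tests."""

    planted_proteins: list[str] = field(default_factory=list)
    directions: dict[str, int] = field(default_factory=dict)  # +1 up in lmCRC
    injected_outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    injected_missing_cells: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "planted_proteins": self.planted_proteins,
            "directions": self.directions,
            "injected_outlier_cells": [list(c) for c in self.injected_outlier_cells],
            "injected_missing_cells": [list(c) for c in self.injected_missing_cells],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_proteins=payload["planted_proteins"],
            directions={k: int(v) for k, v in payload["directions"].items()},
            injected_outlier_cells=[tuple(c) for c in payload["injected_outlier_cells"]],
            injected_missing_cells=[tuple(c) for c in payload["injected_missing_cells"]],
        )


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the sample sheet: study columns, pools, technical replicates."""
    rows = []
    for g, group, n in ((0, GROUP_A, config.n_group_a), (1, GROUP_B, config.n_group_b)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "batch": f"b{(len(rows) % config.n_batches) + 1}",
                    "role": "study",
                    "replicate_of": "",
                }
            )
    study = [r["sample_id"] for r in rows]
    for j in range(config.n_pools):
        rows.append(
            {
                "sample_id": f"POOL_{j + 1}",
                "group": "none",
                "batch": f"b{(j % config.n_batches) + 1}",
                "role": "pool",
                "replicate_of": "",
            }
        )
    n_rep = config.n_intra_replicates + config.n_inter_replicates
    if n_rep > len(study):
        raise ValueError("more technical replicates than study samples")
    sources = rng.choice(study, size=n_rep, replace=False)
    batch_of = {r["sample_id"]: r["batch"] for r in rows}
    for j, src in enumerate(sources):
        intra = j < config.n_intra_replicates
        if intra or config.n_batches == 1:
            batch = batch_of[src]
        else:
            others = [f"b{b + 1}" for b in range(config.n_batches) if f"b{b + 1}" != batch_of[src]]
            batch = others[int(rng.integers(len(others)))]
        rows.append(
            {
                "sample_id": f"REP_{j + 1}_{src}",
                "group": "none",
                "batch": batch,
                "role": "replicate",
                "replicate_of": src,
            }
        )
    return pd.DataFrame(rows)


def simulate_abundance(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate an abundance-ratio matrix, sample sheet and ground truth.

    Returns
    -------
    matrix : DataFrame, proteins x samples
        Positive abundance ratios with NaN for missing cells.
    sheet : DataFrame
        Columns ``sample_id, group, batch, role, replicate_of``.
    truth : GroundTruth
        Planted proteins/directions and injected missing/outlier cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config, rng)
    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]

    planted_idx = np.sort(rng.choice(config.n_proteins, size=config.n_planted, replace=False))
    directions = rng.choice([-1, 1], size=config.n_planted)

    batch_shift = rng.normal(0.0, config.batch_sd, size=(config.n_proteins, config.n_batches))
    batch_index = {f"b{b + 1}": b for b in range(config.n_batches)}

    effect = np.zeros(config.n_proteins)
    effect[planted_idx] = directions * config.effect_log2fc

    study = sheet[sheet.role == "study"]
    log2 = {}
    for _, row in study.iterrows():
        col = batch_shift[:, batch_index[row.batch]].copy()
        if row.group == GROUP_B:
            col = col + effect
        col += rng.normal(0.0, config.noise_sd, size=config.n_proteins)
        log2[row.sample_id] = col

    study_mean = np.mean([log2[s] for s in study.sample_id], axis=0)
    for _, row in sheet[sheet.role == "pool"].iterrows():
        log2[row.sample_id] = (
            study_mean
            + batch_shift[:, batch_index[row.batch]]
            + rng.normal(0.0, config.pool_sd, size=config.n_proteins)
        )
    for _, row in sheet[sheet.role == "replicate"].iterrows():
        src = row.replicate_of
        src_batch = study.loc[study.sample_id == src, "batch"].iloc[0]
        base = log2[src] - batch_shift[:, batch_index[src_batch]]
        log2[row.sample_id] = (
            base
            + batch_shift[:, batch_index[row.batch]]
            + rng.normal(0.0, config.tech_sd, size=config.n_proteins)
        )

    matrix = pd.DataFrame(
        {s: np.exp2(log2[s]) for s in sheet.sample_id}, index=pd.Index(proteins, name="protein")
    )

    truth = GroundTruth(
        planted_proteins=[proteins[i] for i in planted_idx],
        directions={proteins[i]: int(d) for i, d in zip(planted_idx, directions)},
    )

    n_cells = matrix.size
    cells = np.arange(n_cells)
    n_out = int(round(config.outlier_rate * n_cells))
    n_miss = int(round(config.missing_rate * n_cells))
    chosen = rng.choice(cells, size=min(n_out + n_miss, n_cells), replace=False)
    out_cells, miss_cells = chosen[:n_out], chosen[n_out : n_out + n_miss]

    values = matrix.to_numpy()
    r_idx, c_idx = np.unravel_index(out_cells, values.shape)
    # upper-tail outliers: large multiplicative spikes, well above any
    # quartile-based fence of the log2-normal bulk
    values[r_idx, c_idx] *= rng.uniform(6.0, 12.0, size=n_out)
    truth.injected_outlier_cells = [
        (proteins[i], matrix.columns[j]) for i, j in zip(r_idx, c_idx)
    ]
    r_idx, c_idx = np.unravel_index(miss_cells, values.shape)
    values[r_idx, c_idx] = np.nan
    truth.injected_missing_cells = [
        (proteins[i], matrix.columns[j]) for i, j in zip(r_idx, c_idx)
    ]
    matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return matrix, sheet, truth


def _hscore_to_percentages(h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose an H-score into (weak, moderate, strong) percentages.

    Piecewise scheme: scores up to 100 are all-weak staining, 100-200 a
    weak/moderate mix summing to 100% of cells, above 200 a moderate/strong
    mix.  Inverts exactly under weak + 2*moderate + 3*strong.
    """
    h = np.asarray(h, dtype=float)
    weak = np.where(h <= 100, h, np.where(h <= 200, 200 - h, 0.0))
    moderate = np.where(h <= 100, 0.0, np.where(h <= 200, h - 100, 300 - h))
    strong = np.where(h <= 200, 0.0, h - 200)
    return weak, moderate, strong


def simulate_ihc(
    n_a: int,
    n_b: int,
    markers: list[str],
    auc_targets: dict[str, float] | list[float],
    seed: int = 0,
    directions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Generate a per-patient, per-marker IHC staining table.

    Each marker's H-score distributions are drawn from a binormal latent
    model whose class separation is calibrated so the population AUC for
    separating the groups equals ``auc_targets[marker]``; a target of
    exactly 1.0 draws the two groups from disjoint H-score supports.

    Parameters
    ----------
    n_a, n_b : int
        Patients in the PAIM / lmCRC group.
    markers : list of str
        Marker names (one staining column set per marker).
    auc_targets : dict or list
        Target AUC per marker, each in [0.5, 1.0].
    directions : dict, optional
        +1 (default) if the marker stains higher in PAIM, -1 if in lmCRC.

    Returns
    -------
    DataFrame with one row per patient x marker: ``patient_id, group,
    marker, pct_weak, pct_moderate, pct_strong, hscore``.
    """
    if not isinstance(auc_targets, dict):
        auc_targets = dict(zip(markers, auc_targets))
    for m in markers:
        a = auc_targets[m]
        if not 0.5 <= a <= 1.0:
            raise ValueError(f"target AUC for {m} must lie in [0.5, 1.0], got {a}")
    directions = directions or {}
    rng = np.random.default_rng(seed)
    patients = [(f"PT_A{i + 1:03d}", GROUP_A) for i in range(n_a)] + [
        (f"PT_B{i + 1:03d}", GROUP_B) for i in range(n_b)
    ]
    rows = []
    for m in markers:
        a = auc_targets[m]
        d = directions.get(m, 1)
        if a == 1.0:
            hi = rng.uniform(170.0, 300.0, size=n_a + n_b)
            lo = rng.uniform(0.0, 130.0, size=n_a + n_b)
        else:
            # binormal: AUC = Phi(mu / sqrt(2)) for N(mu,1) vs N(0,1)
            mu = np.sqrt(2.0) * ndtri(a)
            z_hi = rng.normal(mu, 1.0, size=n_a + n_b)
            z_lo = rng.normal(0.0, 1.0, size=n_a + n_b)
            hi = 300.0 * expit(1.5 * (z_hi - mu / 2.0))
            lo = 300.0 * expit(1.5 * (z_lo - mu / 2.0))
        for i, (pid, group) in enumerate(patients):
            in_high = (group == GROUP_A) == (d >= 0)
            h = float(hi[i] if in_high else lo[i])
            w, mo, s = _hscore_to_percentages(np.array([h]))
            rows.append(
                {
                    "patient_id": pid,
                    "group": group,
                    "marker": m,
                    "pct_weak": float(w[0]),
                    "pct_moderate": float(mo[0]),
                    "pct_strong": float(s[0]),
                    "hscore": h,
                }
            )
    return pd.DataFrame(rows)
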