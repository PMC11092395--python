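"""Welch test, Benjamini-Hochberg adjustment, DEP calling, UMAP embedding."""

import numpy as np
import pandas as pd
import pytest

from panelforge import bh_adjust, call_deps, embed_umap, tukey_fence_impute, welch_test
from panelforge.differential import _welch_vectorized
from panelforge.simulate import GROUP_A, GROUP_B, SimulationConfig, simulate_abundance

from oracles import bh_oracle, welch_oracle


class TestWelch:
    def test_worked_example(self):
        t, df, p = welch_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1 / np.sqrt(2 / 3))
        assert df == pytest.approx(4.0)

    def test_symmetry(self):
        t1, df1, p1 = welch_test([1.0, 2.5, 3.1], [0.3, 0.9, 2.2, 4.4])
        t2, df2, p2 = welch_test([0.3, 0.9, 2.2, 4.4], [1.0, 2.5, 3.1])
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_insufficient_data_marked_untested(self):
        assert np.isnan(welch_test([1.0], [2.0, 3.0])[2])
        assert np.isnan(welch_test([1.0, 1.0], [2.0, 2.0])[2])  # zero variance

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(0)
        n_rep, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_rep):
            _, _, p = welch_test(rng.normal(size=8), rng.normal(size=6))
            rejections += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) < 3 * se

    def test_agrees_with_textbook_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            x = rng.normal(size=rng.integers(3, 9))
            y = rng.normal(scale=rng.uniform(0.5, 2), size=rng.integers(3, 9))
            got = welch_test(x, y)
            want = welch_oracle(x, y)
            assert got == pytest.approx(want, abs=1e-10)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(2)
        xa = rng.normal(size=(40, 9))
        xb = rng.normal(size=(40, 7))
        xa[rng.random(xa.shape) < 0.1] = np.nan
        t, df, p = _welch_vectorized(xa, xb)
        for i in range(40):
            want = welch_test(xa[i], xb[i])
            if np.isnan(want[0]):
                assert np.isnan(t[i])
            else:
                assert (t[i], df[i], p[i]) == pytest.approx(want, abs=1e-10)


class TestBH:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_oracle_and_properties(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 30))
            adj = bh_adjust(p)
            assert adj == pytest.approx(bh_oracle(p), abs=1e-12)
            assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert adj[[0, 2]] == pytest.approx(bh_oracle([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallDeps:
    def test_flags_consistent_with_strict_thresholds(self, small_dataset):
        matrix, sheet, _ = small_dataset
        table = call_deps(matrix, sheet)
        ok = ~(table.adj_p.isna() | table.log2_fold_change.isna())
        expected = (table.adj_p < 0.05) & (table.log2_fold_change.abs() > 0.25) & ok
        assert (table.is_dep == expected).all()
        # fold change is lmCRC over PAIM
        a = sheet[(sheet.role == "study") & (sheet.group == GROUP_A)].sample_id
        b = sheet[(sheet.role == "study") & (sheet.group == GROUP_B)].sample_id
        prot = table.index[0]
        fc = np.nanmean(matrix.loc[prot, b]) / np.nanmean(matrix.loc[prot, a])
        assert table.loc[prot, "fold_change"] == pytest.approx(fc)

    def test_equal_means_never_dep(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "group": [GROUP_A] * 3 + [GROUP_B] * 3,
                "batch": ["b1"] * 6,
                "role": ["study"] * 6,
                "replicate_of": [""] * 6,
            }
        )
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]], index=["P1"], columns=sheet.sample_id
        )
        table = call_deps(matrix, sheet)
        assert table.loc["P1", "log2_fold_change"] == pytest.approx(0.0)
        assert not table.loc["P1", "is_dep"]

    def test_planted_recovery_and_fdp(self):
        """Planted markers (effect 0.6, noise 0.25, n=22 vs 17) are recovered
        at >= 90% with false-discovery proportion <= 0.10 over 20 seeds."""
        recalls, fdps = [], []
        for seed in range(20):
            cfg = SimulationConfig(
                n_proteins=400, n_planted=20, effect_log2fc=0.6, noise_sd=0.25, seed=seed
            )
            matrix, sheet, truth = simulate_abundance(cfg)
            matrix, _ = tukey_fence_impute(matrix)  # spikes are QC'd first
            table = call_deps(matrix, sheet)
            called = set(table.index[table.is_dep])
            planted = set(truth.planted_proteins)
            recalls.append(len(called & planted) / len(planted))
            fdps.append(len(called - planted) / max(1, len(called)))
        assert np.mean(recalls) >= 0.90
        assert np.mean(fdps) <= 0.10

    def test_invariant_to_row_and_column_order(self, small_dataset):
        matrix, sheet, _ = small_dataset
        t1 = call_deps(matrix, sheet)
        t2 = call_deps(matrix.iloc[::-1, ::-1], sheet)
        pd.testing.assert_series_equal(
            t1.is_dep.sort_index(), t2.is_dep.sort_index()
        )

    def test_one_group_rejected(self, small_dataset):
        matrix, sheet, _ = small_dataset
        only_a = sheet[sheet.group != GROUP_B]
        with pytest.raises(ValueError):
            call_deps(matrix, only_a)


class TestEmbedUMAP:
    @pytest.fixture(scope="class")
    def dep_submatrix(self):
        cfg = SimulationConfig(
            n_proteins=120, n_planted=30, effect_log2fc=1.5, noise_sd=0.2,
            missing_rate=0.0, outlier_rate=0.0, seed=4,
        )
        matrix, sheet, truth = simulate_abundance(cfg)
        study = sheet[sheet.role == "study"]
        return matrix.loc[truth.planted_proteins, study.sample_id], study.group.to_numpy()

    def test_deterministic_for_fixed_seed(self, dep_submatrix):
        m, _ = dep_submatrix
        c1 = embed_umap(m, seed=9)
        c2 = embed_umap(m, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_separated_groups_recovered_by_2means(self, dep_submatrix):
        from sklearn.cluster import KMeans

        m, groups = dep_submatrix
        coords = embed_umap(m, seed=9)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(coords)
        agree = np.mean((km == km[0]) == (groups == groups[0]))
        assert max(agree, 1 - agree) >= 0.95

    def test_duplicate_sample_embeds_adjacent(self, dep_submatrix):
        m, _ = dep_submatrix
        dup = m.copy()
        dup["twin"] = dup.iloc[:, 0]
        coords = embed_umap(dup, seed=9)
        d = ((coords - coords.loc["twin"]) ** 2).sum(axis=1).drop("twin")
        assert d.idxmin() == dup.columns[0]

    def test_empty_dep_set_rejected(self):
        with pytest.raises(ValueError):
            embed_umap(pd.DataFrame(columns=["s1", "s2", "s3"]), seed=0)


def test_null_matrix_controls_dep_count():
    """Under a global null the expected DEP count stays below alpha * m."""
    counts = []
    for seed in range(10):
        cfg = SimulationConfig(n_proteins=300, n_planted=0, seed=seed)
        matrix, sheet, _ = simulate_abundance(cfg)
        table = call_deps(matrix, sheet)
        counts.append(int(table.is_dep.sum()))
    assert np.mean(counts) <= 0.05 * 300
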