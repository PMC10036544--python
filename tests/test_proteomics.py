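"""Proteomics chain: filtering, normalisation, two-pass imputation, testing."""

import numpy as np
import pandas as pd
import pytest

from adhesomics import proteomics as pp
from adhesomics import synthio
from adhesomics.synthio import AbundanceMatrix


def _matrix(values: np.ndarray, n_per_group: int = 3) -> AbundanceMatrix:
    n, m = values.shape
    samples = [f"A{i+1}" for i in range(n_per_group)] + [
        f"B{i+1}" for i in range(m - n_per_group)
    ]
    df = pd.DataFrame(values, index=[f"P{i:04d}" for i in range(n)], columns=samples)
    return AbundanceMatrix(df, {s: s[0] for s in samples})


class TestFilterReplication:
    def test_rule_applied_per_group(self):
        vals = np.full((2, 6), 20.0)
        vals[0, 2:] = np.nan  # 2 of 3 in A, 0 in B -> kept
        vals[1, 1:5] = np.nan  # 1 in A, 1 in B -> dropped
        out = pp.filter_replication(_matrix(vals))
        assert list(out.values.index) == ["P0000"]

    def test_matches_brute_force_census(self):
        m, _ = synthio.gen_lfq_matrix(n_proteins=1000, seed=5)
        out = pp.filter_replication(m, min_present=2)
        expected = []
        for pid, row in m.values.iterrows():
            a = row[["A1", "A2", "A3"]].notna().sum()
            b = row[["B1", "B2", "B3"]].notna().sum()
            if a >= 2 or b >= 2:
                expected.append(pid)
        assert list(out.values.index) == expected

    def test_min_present_too_large_error(self):
        m, _ = synthio.gen_lfq_matrix(n_proteins=20, seed=0)
        with pytest.raises(ValueError):
            pp.filter_replication(m, min_present=4)


class TestRlrNormalize:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.normal(25, 2, 100)
        vals = np.tile(col[:, None], (1, 6))
        out = pp.rlr_normalize(_matrix(vals))
        assert np.allclose(out.values.to_numpy(), vals, atol=1e-8)

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(1)
        col = rng.normal(25, 2, 200)
        vals = np.tile(col[:, None], (1, 6))
        vals[:, 0] += 0.7
        out = pp.rlr_normalize(_matrix(vals))
        assert np.max(np.abs(out.values.to_numpy()[:, 0] - col)) < 1e-6

    def test_robust_to_outliers_where_ols_is_not(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(25, 2, 300)
        vals = np.tile(ref[:, None], (1, 6))
        sample = ref + 0.3
        wild = rng.choice(300, size=30, replace=False)
        sample[wild] += rng.uniform(5, 10, size=30)  # 10% wild outliers
        vals[:, 0] = sample
        out = pp.rlr_normalize(_matrix(vals))
        robust_offset = abs(np.median(out.values.to_numpy()[:, 0] - ref))

        # ordinary least squares on the same draw
        reference = np.median(vals, axis=1)
        coeffs = np.polyfit(reference, sample, 1)
        fitted = np.polyval(coeffs, reference)
        ols_norm = sample - (fitted - reference)
        ols_offset = abs(np.median(ols_norm - ref))
        assert robust_offset < 0.02
        assert ols_offset > 5 * robust_offset

    def test_too_little_overlap_names_sample(self):
        vals = np.full((20, 6), 25.0)
        vals[5:, 0] = np.nan
        with pytest.raises(ValueError, match="A1"):
            pp.rlr_normalize(_matrix(vals))


class TestImputeMnarMin:
    def test_group_all_missing_gets_column_minimum(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 2, (50, 6))
        vals[0, :3] = np.nan  # all of group A missing
        m = _matrix(vals)
        out = pp.impute_mnar_min(m)
        col_min = np.nanmin(vals, axis=0)
        assert np.allclose(out.values.iloc[0, :3], col_min[:3])

    def test_partial_missingness_untouched(self):
        vals = np.full((3, 6), 25.0)
        vals[1, 0] = np.nan
        vals[1, 3] = np.nan
        out = pp.impute_mnar_min(_matrix(vals))
        assert np.isnan(out.values.iloc[1, 0]) and np.isnan(out.values.iloc[1, 3])

    def test_modified_cells_match_brute_force_predicate(self):
        m, _ = synthio.gen_lfq_matrix(n_proteins=800, seed=9)
        m = pp.filter_replication(m)
        out = pp.impute_mnar_min(m)
        changed = m.values.isna() & out.values.notna()
        groups = {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}
        expected = pd.DataFrame(False, index=m.values.index, columns=m.values.columns)
        for cols in groups.values():
            block_missing = m.values[cols].isna().all(axis=1)
            for c in cols:
                expected.loc[block_missing, c] = True
        assert changed.equals(expected)

    def test_empty_column_error(self):
        vals = np.full((4, 6), 25.0)
        vals[:, 2] = np.nan
        with pytest.raises(ValueError):
            pp.impute_mnar_min(_matrix(vals))


class TestImputePmm:
    def test_identity_without_missing(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(25, 2, (30, 6))
        m = _matrix(vals)
        out = pp.impute_pmm(m, seed=0)
        assert out.values.equals(m.values)

    def test_imputed_values_are_observed_donors(self):
        m, _ = synthio.gen_lfq_matrix(n_proteins=400, seed=6)
        m = pp.filter_replication(m)
        m = pp.impute_mnar_min(m)
        out = pp.impute_pmm(m, seed=1)
        assert not out.values.isna().any().any()
        for c in m.values.columns:
            observed = set(m.values[c].dropna().round(12))
            imputed_cells = m.values[c].isna()
            assert set(out.values.loc[imputed_cells, c].round(12)) <= observed

    def test_beats_column_mean_imputation_on_correlated_data(self):
        rng = np.random.default_rng(7)
        n = 300
        base = rng.normal(25, 2, n)
        vals = np.column_stack(
            [base + rng.normal(0, 0.1, n) for _ in range(6)]
        )
        truth = vals.copy()
        mask = rng.random((n, 6)) < 0.2  # MAR
        mask[:, 0] = False  # keep an anchor column complete
        vals[mask] = np.nan
        m = _matrix(vals)
        out = pp.impute_pmm(m, seed=2)
        pmm_rmse = np.sqrt(np.mean((out.values.to_numpy()[mask] - truth[mask]) ** 2))
        col_means = np.nanmean(vals, axis=0)
        mean_rmse = np.sqrt(
            np.mean((np.broadcast_to(col_means, vals.shape)[mask] - truth[mask]) ** 2)
        )
        assert pmm_rmse < mean_rmse

    def test_deterministic(self):
        m, _ = synthio.gen_lfq_matrix(n_proteins=200, seed=8)
        m = pp.filter_replication(m)
        m = pp.impute_mnar_min(m)
        out1 = pp.impute_pmm(m, seed=5)
        out2 = pp.impute_pmm(m, seed=5)
        assert out1.values.equals(out2.values)


class TestDifferentialAbundance:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(10)
        half = rng.normal(25, 2, (100, 3))
        vals = np.hstack([half, half])
        table = pp.differential_abundance(_matrix(vals))
        assert not table["significant"].any()

    def test_fold_gate_blocks_small_effects(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(25, 1, (200, 6))
        vals[0, :3] = [25.000, 25.001, 24.999]
        vals[0, 3:] = [25.500, 25.501, 25.499]  # log2fc = 0.5, tiny p
        table = pp.differential_abundance(_matrix(vals))
        row = table.loc["P0000"]
        assert row["q"] < 0.01
        assert not row["significant"]

    def test_requires_complete_matrix(self):
        vals = np.full((5, 6), 25.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            pp.differential_abundance(_matrix(vals))


class TestEndToEnd:
    def test_log2fc_estimates_nearly_unbiased_under_mnar(self):
        # recovery of planted effects through the full chain
        m, truth = synthio.gen_lfq_matrix(
            n_proteins=2000, effect_log2fc=2.0, mnar_quantile=0.25, seed=1
        )
        _, table = pp.run_prep(m, seed=1)
        planted = sorted(truth.differential_ids & set(table.index))
        bias = (
            table.loc[planted, "log2fc"] - truth.true_log2fc.loc[planted]
        ).mean()
        assert abs(bias) < 0.2

    def test_stage_order_preserves_rows(self):
        m, _ = synthio.gen_lfq_matrix(n_proteins=300, seed=2)
        filtered = pp.filter_replication(m)
        normalized = pp.rlr_normalize(filtered)
        assert list(normalized.values.index) == list(filtered.values.index)
        pass1 = pp.impute_mnar_min(normalized)
        assert list(pass1.values.index) == list(filtered.values.index)
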