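import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wacna import (
    DatasetTag,
    OmicsMatrix,
    apply_filters,
    bh_adjust,
    class_rollup,
    detection_filter,
    differential_analysis,
    fold_change,
    knn_impute,
    qc_rsd_filter,
    wilcoxon_mw,
)

from .conftest import make_matrix, make_metadata


def matrix_with_qc(bio_values, qc_values, metadata, tag=DatasetTag.METABOLOME_POS):
    bio_values = np.asarray(bio_values, dtype=float)
    qc_values = np.asarray(qc_values, dtype=float)
    vals = np.hstack([bio_values, qc_values])
    cols = list(metadata.biological_samples[: bio_values.shape[1]]) + list(
        metadata.qc_samples[: qc_values.shape[1]]
    )
    idx = pd.Index([f"F{i+1:03d}" for i in range(len(vals))], name="analyte_id")
    return OmicsMatrix(tag, pd.DataFrame(vals, index=idx, columns=cols))


class TestQcRsdFilter:
    def test_zero_variance_kept(self, metadata):
        m = matrix_with_qc([[10, 10, 10, 10]], [[100, 100, 100]], metadata)
        rep = qc_rsd_filter(m, metadata)
        assert rep.table.loc["F001", "qc_rsd"] == 0.0
        assert rep.table.loc["F001", "kept"]

    def test_fifty_percent_rsd_removed(self, metadata):
        # sample SD of [50,100,150] is 50, mean 100 -> RSD 50%
        m = matrix_with_qc([[10, 10, 10, 10]], [[50, 100, 150]], metadata)
        rep = qc_rsd_filter(m, metadata)
        assert rep.table.loc["F001", "qc_rsd"] == pytest.approx(50.0)
        assert not rep.table.loc["F001", "kept"]
        assert rep.table.loc["F001", "removal_reason"] == "rsd"

    def test_five_percent_rsd_kept(self, metadata):
        m = matrix_with_qc([[10, 10, 10, 10]], [[95, 100, 105]], metadata)
        rep = qc_rsd_filter(m, metadata)
        assert rep.table.loc["F001", "qc_rsd"] == pytest.approx(5.0)
        assert rep.table.loc["F001", "kept"]

    def test_all_missing_qc_removed(self, metadata):
        m = matrix_with_qc([[10, 10, 10, 10]], [[np.nan, np.nan, np.nan]], metadata)
        rep = qc_rsd_filter(m, metadata)
        assert not rep.table.loc["F001", "kept"]
        assert rep.table.loc["F001", "removal_reason"] == "rsd"
        assert np.isnan(rep.table.loc["F001", "qc_rsd"])

    def test_transcriptome_passthrough_warns(self, metadata):
        m = make_matrix(np.ones((3, 12)), tag=DatasetTag.TRANSCRIPTOME, metadata=metadata)
        with pytest.warns(UserWarning):
            rep = qc_rsd_filter(m, metadata)
        assert rep.table["kept"].all()

    def test_no_qc_samples_errors(self):
        meta = make_metadata(n_per_group=3, n_qc=0)
        m = make_matrix(np.ones((2, 12)), metadata=meta)
        with pytest.raises(ValueError, match="QC"):
            qc_rsd_filter(m, meta)


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "n_detected, expected_kept",
        [(12, True), (6, False), (9, True)],  # 100%, 50%, 75% of 12
    )
    def test_detection_thresholds(self, metadata, n_detected, expected_kept):
        row = np.full(12, np.nan)
        row[:n_detected] = 100.0
        m = make_matrix(row[None, :], metadata=metadata)
        rep = detection_filter(m, metadata, min_detection=0.70)
        assert bool(rep.table.loc["A001", "kept"]) is expected_kept

    def test_fraction_over_biological_samples_only(self, metadata):
        # feature observed in all 12 biological but no QC samples: kept
        bio = np.full((1, 12), 5.0)
        qc = np.full((1, 3), np.nan)
        m = matrix_with_qc(bio, qc, metadata)
        rep = detection_filter(m, metadata)
        assert rep.table.loc["F001", "detection_fraction"] == 1.0

    def test_empty_biological_set_errors(self, metadata):
        qc_only = make_matrix(np.ones((2, 3)), metadata=None)
        qc_only.values.columns = list(metadata.qc_samples)
        with pytest.raises(ValueError):
            detection_filter(qc_only, metadata)


class TestFilterOrderInvariance:
    def test_combined_filters_are_set_intersection(self, metadata):
        rng = np.random.default_rng(0)
        bio = rng.lognormal(3, 1, size=(50, 12))
        bio[rng.random(bio.shape) < 0.4] = np.nan
        qc = rng.lognormal(3, 0.3, size=(50, 3))
        m = matrix_with_qc(bio, qc, metadata)
        _, rep = apply_filters(m, metadata)
        kept_rsd = set(qc_rsd_filter(m, metadata).kept_ids)
        kept_det = set(detection_filter(m, metadata).kept_ids)
        assert set(rep.kept_ids) == kept_rsd & kept_det

    def test_conjunctive_mode_is_union(self, metadata):
        rng = np.random.default_rng(1)
        bio = rng.lognormal(3, 1, size=(40, 12))
        bio[rng.random(bio.shape) < 0.4] = np.nan
        qc = rng.lognormal(3, 0.5, size=(40, 3))
        m = matrix_with_qc(bio, qc, metadata)
        _, rep = apply_filters(m, metadata, conjunctive=True)
        kept_rsd = set(qc_rsd_filter(m, metadata).kept_ids)
        kept_det = set(detection_filter(m, metadata).kept_ids)
        assert set(rep.kept_ids) == kept_rsd | kept_det


def brute_force_knn(values, i, s, k):
    """Independent oracle: nearest analytes by co-observed Euclidean distance."""
    dists = []
    for j in range(values.shape[0]):
        if j == i or np.isnan(values[j, s]):
            continue
        both = ~np.isnan(values[i]) & ~np.isnan(values[j])
        if not both.any():
            continue
        d = np.sqrt(np.sum((values[i, both] - values[j, both]) ** 2))
        dists.append((d, j))
    dists.sort(key=lambda t: t[0])
    chosen = [j for _, j in dists[:k]]
    return np.mean([values[j, s] for j in chosen])


class TestKnnImpute:
    def test_no_missing_identity(self, metadata):
        m = make_matrix(np.arange(24, dtype=float).reshape(4, 6))
        out = knn_impute(m, k=3)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_case_mean_of_three_neighbours(self):
        # target analyte missing at s0; three nearest rows carry 1, 2, 3 there
        vals = np.array(
            [
                [np.nan, 10.0, 20.0, 30.0],
                [1.0, 10.0, 20.0, 30.0],
                [2.0, 10.0, 20.0, 31.0],
                [3.0, 10.0, 20.0, 32.0],
                [50.0, 90.0, 80.0, 70.0],
            ]
        )
        m = make_matrix(vals)
        out = knn_impute(m, k=3)
        assert out.values.iloc[0, 0] == pytest.approx(2.0)

    def test_twin_analyte_exact(self):
        vals = np.array(
            [
                [5.0, 6.0, 7.0, 8.0],
                [5.0, 6.0, np.nan, 8.0],
                [100.0, 90.0, 80.0, 70.0],
            ]
        )
        out = knn_impute(make_matrix(vals), k=1)
        assert out.values.iloc[1, 2] == pytest.approx(7.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(2, 1, size=(25, 10))
        miss = rng.random(vals.shape) < 0.15
        vals[miss] = np.nan
        vals[0, :] = rng.lognormal(2, 1, size=10)  # keep at least one full row
        m = make_matrix(vals)
        out = knn_impute(m, k=3).values.to_numpy()
        for i, s in zip(*np.where(np.isnan(vals))):
            assert out[i, s] == pytest.approx(brute_force_knn(vals, i, s, 3))

    def test_observed_entries_unchanged(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(2, 1, size=(20, 8))
        miss = rng.random(vals.shape) < 0.2
        vals[miss] = np.nan
        m = make_matrix(vals)
        out = knn_impute(m, k=3).values.to_numpy()
        obs = ~np.isnan(vals)
        assert np.array_equal(out[obs], vals[obs])
        assert not np.isnan(out).any()

    def test_fewer_neighbours_falls_back_with_warning(self):
        vals = np.array([[np.nan, 2.0], [1.0, 2.0], [np.nan, 3.0]])
        with pytest.warns(UserWarning, match="fewer than k"):
            out = knn_impute(make_matrix(vals), k=3)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)

    def test_all_missing_analyte_errors(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="no observed value"):
            knn_impute(make_matrix(vals))


def exact_mwu_oracle(a, b):
    """Two-sided exact p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_spec_example_exact(self, metadata):
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        m = make_matrix(vals, metadata=None)
        m.values.columns = ["a1", "a2", "a3", "b1", "b2", "b3"]
        meta = make_metadata(n_per_group=2, n_qc=0)
        p = wilcoxon_mw_direct(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"], meta)
        assert p.iloc[0] == pytest.approx(0.1)

    def test_identical_values_p_one(self, metadata):
        vals = np.full((1, 12), 7.0)
        m = make_matrix(vals, metadata=metadata)
        p = wilcoxon_mw(m, metadata, ("diet", "CON"), ("diet", "HFD"))
        assert p.iloc[0] == 1.0

    def test_group_too_small_errors(self):
        meta = make_metadata(n_per_group=3, n_qc=0)
        m = make_matrix(np.ones((1, 12)), metadata=meta)
        with pytest.raises(ValueError, match=">= 2"):
            wilcoxon_mw(m, meta, ("diet", "CON"), ["S004"])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 3), (5, 4), (5, 5)])
    def test_exact_path_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
            b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)[:n2]
            expected = exact_mwu_oracle(a, b)
            got = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert got == pytest.approx(expected, abs=1e-12)


def wilcoxon_mw_direct(matrix, samples_a, samples_b, metadata):
    return wilcoxon_mw(matrix, metadata, samples_a, samples_b)


class TestBhAdjust:
    def test_spec_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(200)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestFoldChange:
    def test_doubling(self, metadata):
        vals = np.array([[100.0] * 6 + [200.0] * 6])
        m = make_matrix(vals, metadata=metadata)
        fc = fold_change(m, metadata, ("diet", "CON"), ("diet", "HFD"), seed=0)
        assert fc.loc["A001", "fold_change"] == pytest.approx(2.0)

    def test_sign_convention(self, metadata):
        vals = np.array([[200.0] * 6 + [100.0] * 6])
        m = make_matrix(vals, metadata=metadata)
        fc = fold_change(m, metadata, ("diet", "CON"), ("diet", "HFD"), seed=0)
        assert fc.loc["A001", "fold_change"] == pytest.approx(-2.0)

    def test_constant_groups_degenerate_ci(self, metadata):
        vals = np.array([[100.0] * 6 + [300.0] * 6])
        m = make_matrix(vals, metadata=metadata)
        fc = fold_change(m, metadata, ("diet", "CON"), ("diet", "HFD"), seed=0)
        assert fc.loc["A001", "ci_low"] == fc.loc["A001", "ci_high"] == pytest.approx(3.0)

    def test_ci_contains_point(self, metadata):
        rng = np.random.default_rng(11)
        vals = rng.lognormal(4, 0.5, size=(30, 12))
        m = make_matrix(vals, metadata=metadata)
        fc = fold_change(m, metadata, ("diet", "CON"), ("diet", "HFD"), n_boot=500, seed=1)
        assert (fc["ratio_ci_low"] <= fc["ratio"] + 1e-12).all()
        assert (fc["ratio"] <= fc["ratio_ci_high"] + 1e-12).all()
        assert (fc["fold_change"].abs() >= 1.0).all()

    def test_antisymmetry(self, metadata):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(4, 0.5, size=(10, 12))
        m = make_matrix(vals, metadata=metadata)
        ab = fold_change(m, metadata, ("diet", "CON"), ("diet", "HFD"), seed=2)
        ba = fold_change(m, metadata, ("diet", "HFD"), ("diet", "CON"), seed=2)
        np.testing.assert_allclose(ab["fold_change"], -ba["fold_change"], rtol=1e-12)

    def test_zero_mean_errors(self, metadata):
        vals = np.array([[0.0] * 6 + [1.0] * 6])
        m = make_matrix(vals, metadata=metadata)
        with pytest.raises(ValueError, match="zero group mean"):
            fold_change(m, metadata, ("diet", "CON"), ("diet", "HFD"))


class TestClassRollup:
    def _result(self, metadata, n_up=4, n_down=2, n_null=4):
        rows = []
        for i in range(n_up):
            rows.append([100.0] * 6 + [500.0] * 6)
        for i in range(n_down):
            rows.append([500.0] * 6 + [100.0] * 6)
        for i in range(n_null):
            rows.append([100.0] * 12)  # flat -> p = 1
        m = make_matrix(np.array(rows), metadata=metadata)
        return differential_analysis(
            m, metadata, ("diet", "CON"), ("diet", "HFD"), n_boot=100, seed=3
        )

    def test_counts_and_percentages(self, metadata):
        res = self._result(metadata)
        ann = {"A001": "lipid", "A002": "lipid", "A003": "amino acid"}
        roll = class_rollup(res, ann)
        up = roll[roll["direction"] == "up"].set_index("class")
        assert up.loc["lipid", "count"] == 2
        assert up.loc["lipid", "percent"] == pytest.approx(100 * 2 / 4)
        assert up.loc["unknown", "count"] == 1  # A004 unannotated
        assert up["percent"].sum() == pytest.approx(100.0)

    def test_empty_significant_set(self, metadata):
        rng = np.random.default_rng(14)
        m = make_matrix(rng.lognormal(4, 0.2, size=(5, 12)), metadata=metadata)
        res = differential_analysis(
            m, metadata, ("diet", "CON"), ("diet", "HFD"), n_boot=100, seed=4
        )
        roll = class_rollup(res, {})
        assert roll.empty
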