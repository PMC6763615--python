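"""Preprocessing, filtering, Ward/correlation clustering and heatmap export."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from oracles import ward_oracle
from phosphoprofiler import (
    CohortMatrix,
    SimulationConfig,
    cluster_cohort,
    correlation_distance,
    cut_dendrogram,
    filter_significant,
    heatmap_export,
    hierarchical_cluster,
    preprocess_matrix,
    simulate_cohort,
    ward_linkage,
)
from phosphoprofiler.errors import ClusterError, ConfigError, DataError, DistanceError


def two_group_matrix(values, sizes=(3, 3)):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[0])]
    groups = ["A"] * sizes[0] + ["B"] * sizes[1]
    meta = pd.DataFrame({"group": groups, "patient_id": samples, "timepoint": 0}, index=samples)
    cols = [f"k{j}" for j in range(values.shape[1])]
    return CohortMatrix(pd.DataFrame(values, index=samples, columns=cols), meta)


class TestCohortMatrix:
    def test_missing_cells_rejected(self):
        values = np.ones((4, 3))
        values[1, 2] = np.nan
        with pytest.raises(DataError, match="missing"):
            two_group_matrix(values, sizes=(2, 2))

    def test_csv_round_trip(self, rng):
        m = two_group_matrix(rng.uniform(1, 100, size=(6, 4)))
        again = CohortMatrix.from_csv(m.to_csv())
        pd.testing.assert_frame_equal(m.values, again.values)
        assert list(m.groups) == list(again.groups)

    def test_missing_group_column_rejected(self):
        csv = "sample_id,k0,k1\ns1,1.0,2.0\ns2,3.0,4.0\n"
        with pytest.raises(DataError, match="group"):
            CohortMatrix.from_csv(csv)


class TestPreprocess:
    def test_scaled_columns_mean0_sd1(self, rng):
        m = two_group_matrix(rng.uniform(1, 1000, size=(8, 5)), sizes=(4, 4))
        scaled, dropped = preprocess_matrix(m)
        assert dropped == []
        assert np.allclose(scaled.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_analyte_dropped_with_warning(self, rng):
        values = rng.uniform(1, 100, size=(6, 3))
        values[:, 1] = 42.0
        m = two_group_matrix(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, dropped = preprocess_matrix(m, center_samples=False)
        assert dropped == ["k1"]
        assert "k1" not in scaled.columns

    def test_sample_scaling_removed_by_median_centering(self, rng):
        """x4 on one sample: +2 log2 pre-centering, 0 post-centering."""
        values = rng.uniform(10, 1000, size=(5, 7))
        m1 = two_group_matrix(values, sizes=(2, 3))
        boosted = values.copy()
        boosted[0] *= 4.0
        m2 = two_group_matrix(boosted, sizes=(2, 3))
        pre1, _ = preprocess_matrix(m1, pseudocount=0, center_samples=False, scale_analytes=False)
        pre2, _ = preprocess_matrix(m2, pseudocount=0, center_samples=False, scale_analytes=False)
        assert np.allclose(pre2.iloc[0] - pre1.iloc[0], 2.0)
        post1, _ = preprocess_matrix(m1, pseudocount=0, scale_analytes=False)
        post2, _ = preprocess_matrix(m2, pseudocount=0, scale_analytes=False)
        assert np.allclose(post2.iloc[0], post1.iloc[0], atol=1e-9)

    def test_negative_values_rejected(self):
        with pytest.raises(DataError, match="negative"):
            preprocess_matrix(two_group_matrix(-np.ones((4, 2)), sizes=(2, 2)))


class TestFilterSignificant:
    def test_identical_groups_nothing_kept(self, rng):
        half = rng.uniform(1, 100, size=(3, 5))
        m = two_group_matrix(np.vstack([half, half]))
        kept, pvals = filter_significant(m, alpha=0.05)
        assert np.allclose(pvals, 1.0)
        assert kept.values.shape[1] == 0

    def test_alpha_one_keeps_all_testable(self, rng):
        m = two_group_matrix(rng.uniform(1, 100, size=(6, 5)))
        kept, _ = filter_significant(m, alpha=1.0)
        assert kept.values.shape[1] == 5

    def test_more_than_two_groups_rejected(self, rng):
        m = two_group_matrix(rng.uniform(1, 100, size=(6, 3)))
        m.sample_meta.loc["s5", "group"] = "C"
        with pytest.raises(DataError, match="2 groups"):
            filter_significant(m)

    def test_tiny_group_rejected(self, rng):
        m = two_group_matrix(rng.uniform(1, 100, size=(5, 3)), sizes=(1, 4))
        with pytest.raises(DataError, match="fewer than 2"):
            filter_significant(m)

    def test_planted_effect_kept(self, rtk_layout):
        hits, total = 0, 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, effect_size=3.0, measurement_log2_sd=0.1)
            matrix, truth = simulate_cohort(cfg, rtk_layout)
            kept, _ = filter_significant(matrix)
            kept_set = set(kept.analytes)
            for analytes in truth.affected_sets.values():
                total += len(analytes)
                hits += len(kept_set.intersection(analytes))
        assert hits / total >= 0.95


class TestCorrelationDistance:
    def test_identity_zero(self):
        x = np.array([1.0, 2.0, 5.0])
        assert correlation_distance(x, x) == pytest.approx(0.0)

    def test_anticorrelation_two(self):
        x = np.array([1.0, 2.0, 5.0])
        assert correlation_distance(x, -x) == pytest.approx(2.0)

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert correlation_distance(x, 3.0 * x + 7.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DistanceError):
            correlation_distance(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestWardLinkage:
    def test_identical_rows_merge_first_at_zero(self, rng):
        base = rng.normal(size=6)
        rows = np.vstack([base, base + rng.normal(size=6) * 2, base])
        m = pd.DataFrame(rows.T, columns=["a", "b", "c"])
        dend = hierarchical_cluster(m, axis="analytes")
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 2}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_leaf_count_conserved(self, rng):
        m = pd.DataFrame(rng.normal(size=(7, 9)))
        dend = hierarchical_cluster(m, axis="samples")
        assert dend.n_leaves == 7
        assert sorted(dend.leaf_order()) == sorted(dend.labels)

    def test_two_separated_groups_merge_within_first(self, rng):
        """4 rows in two correlation groups: first two merges intra-group."""
        t = np.linspace(0, 1, 10)
        up = np.vstack([t + rng.normal(0, 0.01, 10) for _ in range(2)])
        down = np.vstack([-t + rng.normal(0, 0.01, 10) for _ in range(2)])
        m = pd.DataFrame(np.vstack([up, down]).T)
        dend = hierarchical_cluster(m, axis="analytes")
        first_two = {frozenset((int(r[0]), int(r[1]))) for r in dend.linkage[:2]}
        assert first_two == {frozenset((0, 1)), frozenset((2, 3))}

    def test_matches_brute_force_oracle(self, rng):
        """Merge sequence and heights equal exhaustive agglomeration."""
        for _ in range(30):
            n = int(rng.integers(3, 7))
            X = rng.normal(size=(n, 8))
            D = 1.0 - np.corrcoef(X)
            np.fill_diagonal(D, 0.0)
            Z = ward_linkage(D)
            expected = ward_oracle(D)
            for row, (i, j, h) in zip(Z, expected):
                assert (int(row[0]), int(row[1])) == (i, j)
                assert row[2] == pytest.approx(h, abs=1e-9)

    def test_heights_match_scipy_ward(self, rng):
        """Independent cross-check against scipy's Ward implementation."""
        for _ in range(10):
            n = int(rng.integers(4, 10))
            X = rng.normal(size=(n, 12))
            D = 1.0 - np.corrcoef(X)
            np.fill_diagonal(D, 0.0)
            ours = np.sort(ward_linkage(D)[:, 2])
            theirs = np.sort(scipy_linkage(squareform(D, checks=False), method="ward")[:, 2])
            assert np.allclose(ours, theirs, atol=1e-9)

    def test_heights_monotone(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 15)))
        dend = hierarchical_cluster(m, axis="samples")
        heights = dend.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_constant_vector_named_in_error(self, rng):
        values = rng.normal(size=(5, 4))
        values[:, 2] = 3.0
        m = pd.DataFrame(values, columns=["a", "b", "weird", "d"])
        with pytest.raises(ClusterError, match="weird"):
            hierarchical_cluster(m, axis="analytes")


class TestCutDendrogram:
    def _dend(self, rng, n=8):
        m = pd.DataFrame(rng.normal(size=(n, 10)), index=[f"s{i}" for i in range(n)])
        return hierarchical_cluster(m, axis="samples")

    def test_k1_single_cluster(self, rng):
        dend = self._dend(rng)
        assert set(cut_dendrogram(dend, 1).values()) == {0}

    def test_k_equals_leaves_singletons(self, rng):
        dend = self._dend(rng)
        assignment = cut_dendrogram(dend, dend.n_leaves)
        assert len(set(assignment.values())) == dend.n_leaves

    def test_invalid_k(self, rng):
        dend = self._dend(rng)
        with pytest.raises(ConfigError):
            cut_dendrogram(dend, 0)
        with pytest.raises(ConfigError):
            cut_dendrogram(dend, 99)

    def test_stable_under_leaf_reordering(self, rng):
        values = rng.normal(size=(6, 10))
        labels = [f"s{i}" for i in range(6)]
        m1 = pd.DataFrame(values, index=labels)
        perm = rng.permutation(6)
        m2 = pd.DataFrame(values[perm], index=[labels[i] for i in perm])
        cut1 = cut_dendrogram(hierarchical_cluster(m1, axis="samples"), 3)
        cut2 = cut_dendrogram(hierarchical_cluster(m2, axis="samples"), 3)
        assert cut1 == cut2

    def test_planted_groups_recovered(self, rtk_layout):
        aris = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, effect_size=3.0, measurement_log2_sd=0.1)
            matrix, truth = simulate_cohort(cfg, rtk_layout)
            result = cluster_cohort(matrix)
            cut = cut_dendrogram(result.col_dendrogram, 2)
            samples = list(truth.group_labels.index)
            aris.append(
                adjusted_rand_score(
                    truth.group_labels.loc[samples], [cut[s] for s in samples]
                )
            )
        assert np.mean(aris) >= 0.9


class TestHeatmapExport:
    def _result(self, rng, seed=0):
        cfg = SimulationConfig(seed=seed, effect_size=3.0)
        matrix, _ = simulate_cohort(cfg)
        return cluster_cohort(matrix)

    def test_values_within_plus_minus_3(self, rng):
        bundle = heatmap_export(self._result(rng))
        assert bundle["matrix"].to_numpy().min() >= -3.0
        assert bundle["matrix"].to_numpy().max() <= 3.0

    def test_scaled_rows_mean0_sd1_before_clipping(self, rng):
        result = self._result(rng)
        assert np.allclose(result.scaled.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(result.scaled.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_reordering_is_a_permutation(self, rng):
        result = self._result(rng)
        bundle = heatmap_export(result)
        assert sorted(bundle["row_order"]) == sorted(result.scaled.index)
        assert sorted(bundle["col_order"]) == sorted(result.scaled.columns)
        original = result.scaled.clip(-3, 3)
        assert np.allclose(
            bundle["matrix"].loc[result.scaled.index, result.scaled.columns], original
        )

    def test_csv_round_trip_bit_identical(self, rng, tmp_path):
        result = self._result(rng)
        bundle = heatmap_export(result, outdir=tmp_path)
        again = pd.read_csv(tmp_path / "heatmap.csv", index_col=0)
        assert np.allclose(again.to_numpy(), bundle["matrix"].to_numpy(), atol=1e-12)

    def test_newick_exported_with_all_leaves(self, rng, tmp_path):
        result = self._result(rng)
        heatmap_export(result, outdir=tmp_path)
        newick = (tmp_path / "cols.nwk").read_text()
        for sample in result.scaled.columns:
            assert sample in newick


class TestNullBehaviour:
    def test_null_effect_ari_near_chance_and_alpha_rate_filter(self, rtk_layout):
        aris, kept_frac = [], []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, effect_size=0.0)
            matrix, truth = simulate_cohort(cfg, rtk_layout)
            _, pvals = filter_significant(matrix)
            kept_frac.append(float((pvals < 0.05).mean()))
            # unfiltered: the supervised filter would reintroduce the labels
            result = cluster_cohort(matrix, alpha=1.0)
            cut = cut_dendrogram(result.col_dendrogram, 2)
            samples = list(truth.group_labels.index)
            aris.append(
                adjusted_rand_score(
                    truth.group_labels.loc[samples], [cut[s] for s in samples]
                )
            )
        assert np.mean(aris) <= 0.2
        se = np.sqrt(0.05 * 0.95 / (20 * 49))
        assert abs(np.mean(kept_frac) - 0.05) <= 3 * se
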