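"""Quantile normalization, differential testing and the volcano filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from lncvsd.expression import (
    DifferentialRecord,
    ExpressionMatrix,
    differential_test,
    quantile_normalize,
    sample_dendrogram,
    volcano_filter,
)
from lncvsd.synthetic import SimulationConfig, generate_expression
from lncvsd.genomic_context import TranscriptModel


def matrix_from(values, groups, log2=True, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or list(groups)
    df = pd.DataFrame(values, index=probes, columns=samples)
    return ExpressionMatrix(df, groups, log2=log2)


def dummy_lnc_annotation(n):
    return [
        TranscriptModel(f"p{i:05d}", "chr1", "+", i * 10_000, i * 10_000 + 1_000,
                        ((i * 10_000, i * 10_000 + 1_000),), "lncRNA")
        for i in range(n)
    ]


class TestQuantileNormalize:
    def test_two_by_two_hand_example(self):
        m = matrix_from([[1, 4], [3, 2]], {"A": "VSD", "NC1": "NC"}, samples=["A", "NC1"])
        out = quantile_normalize(m)
        assert np.allclose(out.values["A"], [1.5, 3.5])
        assert np.allclose(out.values["NC1"], [3.5, 1.5])

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.uniform(4, 14, (200, 6)),
                        {f"s{i}": ("VSD" if i < 3 else "NC") for i in range(6)},
                        samples=[f"s{i}" for i in range(6)])
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.values.to_numpy(), axis=0)
        assert np.all(np.ptp(sorted_cols, axis=1) < 1e-9)
        assert np.allclose(out.values.sum(axis=0), out.values.sum(axis=0).iloc[0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.uniform(4, 14, (150, 4)),
                        {f"s{i}": ("VSD" if i < 2 else "NC") for i in range(4)},
                        samples=[f"s{i}" for i in range(4)])
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_identical_columns_unchanged(self):
        col = np.array([2.0, 5.0, 9.0])
        m = matrix_from(np.column_stack([col, col]), {"a": "VSD", "b": "NC"},
                        samples=["a", "b"])
        out = quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), np.column_stack([col, col]))

    def test_single_column_unchanged(self):
        m = matrix_from([[1.0], [7.0], [3.0]], {"a": "VSD"}, samples=["a"])
        assert np.allclose(quantile_normalize(m).values["a"], [1.0, 7.0, 3.0])

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["p"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(df, {"a": "VSD", "b": "NC"}, log2=True)


class TestDifferentialTest:
    GROUPS6 = {"v1": "VSD", "v2": "VSD", "v3": "VSD", "n1": "NC", "n2": "NC", "n3": "NC"}

    def test_textbook_two_sample_t(self):
        # (1,2,3) vs (4,5,6): equal variances, df = 4, t = -3/sqrt(2/3)
        m = matrix_from([[1, 2, 3, 4, 5, 6]], self.GROUPS6)
        r = differential_test(m)[0]
        assert r.log2fc == pytest.approx(-3.0)
        assert r.p_value == pytest.approx(0.021311641128756713, abs=1e-12)
        assert r.direction == "down"

    def test_matches_scipy_welch_on_random_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(8, 1, (50, 6))
        m = matrix_from(X, self.GROUPS6)
        records = differential_test(m)
        _, p_ref = stats.ttest_ind(X[:, :3], X[:, 3:], axis=1, equal_var=False)
        assert np.allclose([r.p_value for r in records], p_ref, atol=1e-12)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(8)
        X = rng.normal(8, 1, (30, 6))
        m = matrix_from(X, self.GROUPS6)
        records = differential_test(m, paired=True)
        _, p_ref = stats.ttest_rel(X[:, :3], X[:, 3:], axis=1)
        assert np.allclose([r.p_value for r in records], p_ref, atol=1e-12)

    def test_noiseless_identical_groups(self):
        m = matrix_from([[5, 5, 5, 5, 5, 5], [8, 8, 8, 8, 8, 8]], self.GROUPS6)
        for r in differential_test(m):
            assert r.log2fc == 0.0
            assert r.variance_floored
            assert np.isfinite(r.p_value)

    def test_fewer_than_two_per_group_rejected(self):
        m = matrix_from([[1, 2, 3]], {"v1": "VSD", "v2": "VSD", "n1": "NC"},
                        samples=["v1", "v2", "n1"])
        with pytest.raises(ValueError, match=">=2"):
            differential_test(m)

    def test_planted_effect_estimated_within_tolerance(self):
        config = SimulationConfig(seed=21, n_replicates_per_group=5, noise_sd=0.1,
                                  planted_log2fc=2.0, fraction_de=0.2)
        annotation = dummy_lnc_annotation(500)
        matrix, truth = generate_expression(config, annotation)
        records = {r.probe_id: r for r in differential_test(matrix)}
        hits = [
            abs(records[pid].log2fc - sign * 2.0) <= 0.3
            for pid, sign in truth.true_de_probes.items()
        ]
        assert np.mean(hits) >= 0.95


class TestVolcanoFilter:
    def rec(self, pid, fc, p, direction="up"):
        lfc = np.log2(fc) * (1 if direction == "up" else -1)
        return DifferentialRecord(pid, lfc, fc, p, direction)

    def test_basic_partition(self):
        records = [self.rec("a", 4, 0.001, "up"), self.rec("b", 4, 0.001, "down"),
                   self.rec("c", 1.5, 0.001, "up"), self.rec("d", 4, 0.2, "up")]
        up, down = volcano_filter(records)
        assert up == ["a"] and down == ["b"]
        assert not set(up) & set(down)

    def test_thresholds_are_strict(self):
        records = [self.rec("at_fc", 2.0, 0.001), self.rec("at_p", 4.0, 0.05)]
        up, down = volcano_filter(records)
        assert up == [] and down == []

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            volcano_filter([], fc_threshold=0.0)
        with pytest.raises(ValueError):
            volcano_filter([], p_threshold=-0.1)

    def test_noiseless_planted_lists_recovered_exactly(self):
        config = SimulationConfig(seed=5, n_replicates_per_group=3, noise_sd=0.0,
                                  planted_log2fc=2.0, fraction_de=0.3)
        annotation = dummy_lnc_annotation(200)
        matrix, truth = generate_expression(config, annotation)
        up, down = volcano_filter(differential_test(matrix))
        expect_up = {p for p, s in truth.true_de_probes.items() if s > 0}
        expect_down = {p for p, s in truth.true_de_probes.items() if s < 0}
        assert set(up) == expect_up and set(down) == expect_down


class TestDendrogram:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(4, 12, 30)
        X = np.column_stack([col, col, rng.uniform(4, 12, 30), rng.uniform(4, 12, 30)])
        m = matrix_from(X, {"a": "VSD", "b": "VSD", "c": "NC", "d": "NC"},
                        samples=["a", "b", "c", "d"])
        Z, _ = sample_dendrogram(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_three_samples_match_manual_linkage(self):
        X = np.array([[1.0, 1.1, 5.0], [2.0, 2.1, 1.0], [3.0, 2.9, 4.0], [4.0, 4.2, 2.0]])
        m = matrix_from(X, {"a": "VSD", "b": "VSD", "c": "NC"}, samples=["a", "b", "c"])
        Z, _ = sample_dendrogram(m)
        corr = np.corrcoef(X.T)
        d_ab, d_ac, d_bc = 1 - corr[0, 1], 1 - corr[0, 2], 1 - corr[1, 2]
        assert Z[0, 2] == pytest.approx(d_ab)          # closest pair first
        assert Z[1, 2] == pytest.approx((d_ac + d_bc) / 2)  # average linkage

    def test_planted_groups_separate_first(self):
        config = SimulationConfig(seed=13, n_replicates_per_group=4, noise_sd=0.2,
                                  planted_log2fc=2.0, fraction_de=0.3)
        matrix, _ = generate_expression(config, dummy_lnc_annotation(300))
        Z, _ = sample_dendrogram(matrix)
        clusters = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        labels = [matrix.group_of_sample[s] for s in matrix.sample_ids]
        split = {g: {clusters[i] for i, l in enumerate(labels) if l == g} for g in ("VSD", "NC")}
        assert len(split["VSD"]) == 1 and len(split["NC"]) == 1
        assert split["VSD"] != split["NC"]

    def test_constant_sample_rejected_by_name(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        m = matrix_from(X, {"flat": "VSD", "ok": "NC"}, samples=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            sample_dendrogram(m)
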