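import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfsynergy.expression import (ExpressionTimeSeries, load_expression_matrix,
                                  load_gs_network, make_lagged_dataset,
                                  split_train_test, reserved_test_timepoints,
                                  write_expression_matrix, zscore_normalize)
from tfsynergy.synthetic import default_config, generate_timeseries


def _write_tiny(tmp_path, matrix_text, meta_text):
    m = tmp_path / "m.tsv"
    s = tmp_path / "s.tsv"
    m.write_text(matrix_text)
    s.write_text(meta_text)
    return m, s


class TestLoadExpressionMatrix:
    def test_parses_one_batch(self, tmp_path):
        m, s = _write_tiny(
            tmp_path,
            "gene\ts0\ts1\ts2\ts3\nA\t1\t2\t3\t4\nB\t4\t3\t2\t1\nC\t1\t1\t2\t2\n",
            "sample\tbatch\ttimepoint\ns0\tb1\t0\ns1\tb1\t1\ns2\tb1\t2\ns3\tb1\t3\n",
        )
        series = load_expression_matrix(m, s, tf_ids=["A"])
        assert series.gene_ids == ["A", "B", "C"]
        assert series.batches == ["b1"]
        assert series.batch_length("b1") == 4

    def test_two_batches_restart_at_zero(self, tmp_path):
        cols = [f"x{i}" for i in range(9)]
        header = "gene\t" + "\t".join(cols)
        meta_lines = ["sample\tbatch\ttimepoint"]
        meta_lines += [f"x{i}\tb1\t{i}" for i in range(5)]
        meta_lines += [f"x{i + 5}\tb2\t{i}" for i in range(4)]
        m, s = _write_tiny(tmp_path,
                           header + "\nA\t" + "\t".join("1" for _ in cols) + "\n",
                           "\n".join(meta_lines) + "\n")
        series = load_expression_matrix(m, s)
        assert series.batch_length("b1") == 5
        assert series.batch_length("b2") == 4

    def test_skipped_timepoint_rejected(self, tmp_path):
        m, s = _write_tiny(
            tmp_path,
            "gene\ts0\ts1\ts2\nA\t1\t2\t3\n",
            "sample\tbatch\ttimepoint\ns0\tb1\t0\ns1\tb1\t1\ns2\tb1\t3\n",
        )
        with pytest.raises(ValueError, match="non-consecutive"):
            load_expression_matrix(m, s)

    def test_unmapped_column_named_in_error(self, tmp_path):
        m, s = _write_tiny(
            tmp_path,
            "gene\ts0\ts1\nA\t1\t2\n",
            "sample\tbatch\ttimepoint\ns0\tb1\t0\n",
        )
        with pytest.raises(ValueError, match="s1"):
            load_expression_matrix(m, s)

    def test_non_numeric_cell_located(self, tmp_path):
        m, s = _write_tiny(
            tmp_path,
            "gene\ts0\ts1\nA\t1\toops\n",
            "sample\tbatch\ttimepoint\ns0\tb1\t0\ns1\tb1\t1\n",
        )
        with pytest.raises(ValueError, match="A.*s1"):
            load_expression_matrix(m, s)

    def test_duplicate_gene_rejected(self, tmp_path):
        m, s = _write_tiny(
            tmp_path,
            "gene\ts0\ts1\nA\t1\t2\nA\t3\t4\n",
            "sample\tbatch\ttimepoint\ns0\tb1\t0\ns1\tb1\t1\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_expression_matrix(m, s)


class TestZscore:
    def test_hand_computed_values(self, tiny_series):
        zseries, params = zscore_normalize(tiny_series, fit_partition="all")
        # TPM [1,2,3,4]: mu=2.5, population sigma=sqrt(1.25)
        expected = (np.array([1, 2, 3, 4]) - 2.5) / np.sqrt(1.25)
        np.testing.assert_allclose(zseries.values.loc["TFA"], expected, atol=1e-12)

    def test_population_sigma_three_points(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"],
                              columns=["s0", "s1", "s2"])
        meta = pd.DataFrame({"batch": ["b"] * 3, "timepoint": [0, 1, 2]},
                            index=values.columns)
        series = ExpressionTimeSeries(values=values, sample_meta=meta, space="tpm")
        z, _ = zscore_normalize(series, fit_partition="all")
        np.testing.assert_allclose(z.values.loc["A"], [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)

    def test_constant_gene_flagged_and_removed(self, tiny_series):
        zseries, params = zscore_normalize(tiny_series, fit_partition="all")
        assert params.degenerate_genes == ["CONST"]
        assert "CONST" not in zseries.gene_ids

    def test_fit_partition_mean_zero_sd_one(self, tiny_series):
        zseries, _ = zscore_normalize(tiny_series, fit_partition="all")
        vals = zseries.values.loc["G1"]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.std(ddof=0) - 1.0) < 1e-10

    def test_train_only_fit_excludes_tail(self, tiny_series):
        # batch of 4 timepoints: t3 is the test target, so mu/sigma use t0..t2
        zseries, params = zscore_normalize(tiny_series, fit_partition="train_only")
        fit = tiny_series.values.loc["G1", ["s0", "s1", "s2"]]
        assert params.mu["G1"] == pytest.approx(fit.mean())
        assert params.sigma["G1"] == pytest.approx(fit.std(ddof=0))

    def test_double_normalization_rejected(self, tiny_series):
        zseries, _ = zscore_normalize(tiny_series, fit_partition="all")
        with pytest.raises(ValueError, match="already"):
            zscore_normalize(zseries)

    def test_inverse_recovers_tpm(self, tiny_series):
        zseries, params = zscore_normalize(tiny_series, fit_partition="all")
        back = params.inverse(zseries.values)
        np.testing.assert_allclose(back, tiny_series.values.loc[zseries.gene_ids],
                                   atol=1e-8)


class TestTailSplit:
    @pytest.mark.parametrize("n, expected_test", [
        (1, {1}), (2, {2}), (4, {4}),          # short series: only t_n
        (5, {4, 5}), (7, {6, 7}), (9, {8, 9}),  # mid: last two
        (10, {8, 9, 10}), (12, {10, 11, 12}),   # long: last three
    ])
    def test_rule(self, n, expected_test):
        assert reserved_test_timepoints(n) == expected_test
        labels = split_train_test(n)
        assert {t for t, p in labels.items() if p == "test"} == expected_test
        assert set(labels) == set(range(1, n + 1))

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError):
            reserved_test_timepoints(0)

    @given(n=st.integers(min_value=1, max_value=60))
    @settings(deadline=None, max_examples=60)
    def test_test_pairs_are_a_suffix(self, n):
        labels = split_train_test(n)
        seq = [labels[t] for t in range(1, n + 1)]
        first_test = seq.index("test")
        assert all(p == "test" for p in seq[first_test:])
        assert all(p == "train" for p in seq[:first_test])


class TestLaggedDataset:
    def test_pair_counts_and_partition(self):
        series, _ = generate_timeseries(default_config(3, batches=(5, 3)))
        data = make_lagged_dataset(series)
        assert len(data.pairs) == 4 + 2
        assert data.n_test() == 2  # one tail pair per batch (n=4 and n=2)
        assert set(data.pairs["batch"]) == {"B1", "B2"}

    def test_no_cross_batch_pairs(self):
        series, _ = generate_timeseries(default_config(3, batches=(5, 3)))
        data = make_lagged_dataset(series)
        for pid, row in data.pairs.iterrows():
            assert row["target_t"] == row["input_t"] + 1

    def test_x_is_input_timepoint_y_is_next(self):
        series, _ = generate_timeseries(default_config(4, batches=(4,)))
        data = make_lagged_dataset(series)
        pid = data.pairs.index[0]
        row = data.pairs.loc[pid]
        s_in = series.sample_at(row["batch"], row["input_t"])
        s_out = series.sample_at(row["batch"], row["target_t"])
        np.testing.assert_array_equal(data.X.loc[pid],
                                      series.values.loc[series.tf_ids, s_in])
        np.testing.assert_array_equal(data.Y.loc[pid], series.values[s_out])

    def test_empty_tf_list_rejected(self):
        series, _ = generate_timeseries(default_config(3, batches=(4,)))
        series.tf_ids = []
        with pytest.raises(ValueError, match="TF"):
            make_lagged_dataset(series)

    def test_requires_zscore_space(self):
        series, _ = generate_timeseries(default_config(3, emit_space="tpm",
                                                       batches=(4,)))
        with pytest.raises(ValueError, match="z-score"):
            make_lagged_dataset(series)


class TestRoundTrip:
    def test_write_then_read_identical(self, tmp_path):
        series, _ = generate_timeseries(default_config(5, batches=(6, 4)))
        write_expression_matrix(series, tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = load_expression_matrix(tmp_path / "m.tsv", tmp_path / "s.tsv",
                                      tf_ids=series.tf_ids, space="zscore")
        pd.testing.assert_frame_equal(back.values, series.values, atol=1e-12,
                                      check_exact=False)
        assert list(back.sample_meta["batch"]) == list(series.sample_meta["batch"])
        assert list(back.sample_meta["timepoint"]) == list(
            series.sample_meta["timepoint"])


class TestGoldStandard:
    def _series(self):
        series, _ = generate_timeseries(default_config(1, batches=(4,)))
        return series

    def test_filters_absent_genes(self, tmp_path):
        series = self._series()
        p = tmp_path / "gs.tsv"
        p.write_text("tf\ttarget\nTF001\tG001\nTF002\tG002\nNOPE\tG001\n")
        gs = load_gs_network(p, series)
        assert len(gs.edges) == 2
        assert gs.n_dropped == 1

    def test_in_degree_counts_distinct_tfs(self, tmp_path):
        series = self._series()
        p = tmp_path / "gs.tsv"
        p.write_text("tf\ttarget\nTF001\tG001\nTF002\tG001\nTF003\tG001\n"
                     "TF001\tG001\n")  # duplicate line
        gs = load_gs_network(p, series)
        assert gs.in_degree["G001"] == 3
        assert len(gs.edges) == 3

    def test_zero_surviving_edges_is_error(self, tmp_path):
        series = self._series()
        p = tmp_path / "gs.tsv"
        p.write_text("tf\ttarget\nX\tY\n")
        with pytest.raises(ValueError, match="no gold-standard edge"):
            load_gs_network(p, series)
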