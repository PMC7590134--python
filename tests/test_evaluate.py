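"""Evaluation harness: entropy, CR arithmetic, rank and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imucodec.evaluate import (
    NEMENYI_Q_05,
    anova_tukey,
    bandwidth_mbps,
    compression_ratio,
    first_order_entropy,
    friedman_test,
    nemenyi_posthoc,
    rank_matrix,
    run_benchmark,
    symbol_entropy,
)
from imucodec.synthetic import generate_corpus

pytestmark = pytest.mark.filterwarnings("ignore:.*clipped.*:UserWarning")


class TestEntropy:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ((0.5, 0.5), 1.0),
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((0.25, 0.75), 0.8112781244591328),
            ((1.0,), 0.0),
            ((0.3, 0.7, 0.0), 0.8812908992306927),   # 0 log 0 = 0
        ],
    )
    def test_known_distributions(self, weights, expected):
        assert first_order_entropy(np.array(weights)) == pytest.approx(expected)

    def test_counts_and_probabilities_agree(self):
        counts = np.array([10, 30, 60])
        assert first_order_entropy(counts) == pytest.approx(
            first_order_entropy(counts / counts.sum())
        )
        assert symbol_entropy(np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            first_order_entropy(np.array([0.5, -0.5]))


class TestCompressionRatio:
    def test_examples(self):
        assert compression_ratio(4200, 420) == 10.0
        assert compression_ratio(100, 100) == 1.0

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            compression_ratio(0, 10)

    def test_full_body_streaming_figure(self):
        assert bandwidth_mbps(500, 15, 9, 32) == pytest.approx(2.16)


class TestFriedman:
    def test_identical_methods_give_null_result(self):
        cr = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        result = friedman_test(cr)
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_hand_evaluated_three_by_three(self):
        """One method always best, one always worst: rank sums (3, 6, 9)
        give chi2 = 12/36 * 126 - 36 = 6."""
        cr = pd.DataFrame(
            [[3.0, 2.0, 1.0]] * 3, columns=["best", "mid", "worst"]
        )
        result = friedman_test(cr)
        assert result.statistic == pytest.approx(6.0)
        assert result.mean_ranks.tolist() == [1.0, 2.0, 3.0]

    def test_matches_scipy_on_continuous_data(self, rng):
        cr = pd.DataFrame(rng.normal(10, 2, size=(20, 4)), columns=list("wxyz"))
        ours = friedman_test(cr)
        ref_stat, ref_p = stats.friedmanchisquare(*[cr[c] for c in cr.columns])
        assert ours.statistic == pytest.approx(ref_stat, abs=1e-9)
        assert ours.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_row_ranks_are_permutations_with_tie_correction(self, rng):
        cr = pd.DataFrame(rng.normal(size=(10, 5)))
        cr.iloc[0, 0] = cr.iloc[0, 1]      # force one tie
        ranks = rank_matrix(cr)
        k = cr.shape[1]
        np.testing.assert_allclose(ranks.sum(axis=1), k * (k + 1) / 2)


class TestNemenyi:
    def test_critical_difference_shrinks_with_corpus_size(self):
        ranks = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        cds = [nemenyi_posthoc(ranks, n).critical_difference for n in (10, 100, 10000)]
        assert cds[0] > cds[1] > cds[2]
        assert cds[2] < 0.1

    def test_identical_mean_ranks_flag_nothing(self):
        ranks = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        assert not nemenyi_posthoc(ranks, 50).significant.values.any()

    def test_embedded_critical_values_match_studentized_range(self):
        for k, q in NEMENYI_Q_05.items():
            ref = stats.studentized_range.ppf(0.95, k, 1e7) / np.sqrt(2)
            assert q == pytest.approx(ref, abs=5e-3)

    def test_separated_ranks_flagged_at_k2(self):
        ranks = pd.Series([1.0, 2.0], index=list("ab"))
        result = nemenyi_posthoc(ranks, 100)
        assert result.critical_difference == pytest.approx(
            1.960 * np.sqrt(6 / (6 * 100)), abs=1e-9
        )
        assert result.significant.loc["a", "b"]


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        groups = {"a": np.full(5, 3.0), "b": np.full(5, 3.0)}
        result = anova_tukey(groups)
        assert result.f_statistic == 0.0
        assert not result.significant.values.any()

    def test_well_separated_groups_flagged(self, rng):
        groups = {
            "stationary": rng.normal(18, 1, 50),
            "active": rng.normal(10, 1, 50),
        }
        result = anova_tukey(groups)
        assert result.p_value < 0.05
        assert result.significant.loc["stationary", "active"]

    def test_only_shifted_class_flagged_among_three(self, rng):
        groups = {
            "a": rng.normal(10, 1, 60),
            "b": rng.normal(10, 1, 60),
            "c": rng.normal(14, 1, 60),
        }
        result = anova_tukey(groups)
        assert result.significant.loc["a", "c"] and result.significant.loc["b", "c"]
        assert not result.significant.loc["a", "b"]

    def test_undersized_class_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestBenchmark:
    def test_single_case_corpus_warns_and_skips_statistics(self):
        corpus = generate_corpus(1, stationary_fraction=0.0, seed=0, duration_s=1.0)
        with pytest.warns(UserWarning, match="single-case"):
            report = run_benchmark(corpus)
        assert report.friedman is None
        assert len(report.cases) > 0

    def test_csv_baseline_has_unit_cr_and_accounting_is_exact(self):
        corpus = generate_corpus(4, seed=1, duration_s=2.0)
        report = run_benchmark(corpus)
        csv_rows = report.cases[report.cases.method == "csv"]
        assert (csv_rows.cr == 1.0).all()
        assert (csv_rows.compressed_bytes == csv_rows.csv_bytes).all()
        binary_rows = report.cases[report.cases.method == "binary"]
        assert (binary_rows.cr == 3.5).all()

    def test_failures_recorded_not_fatal(self):
        corpus = generate_corpus(2, seed=1, duration_s=1.0)
        report = run_benchmark(corpus, methods=("delta", "linear"))
        assert report.failures == []
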