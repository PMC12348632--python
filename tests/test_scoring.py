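"""Best-worst counting analysis, normalization, and the Friedman test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import friedmanchisquare

from qolbws import (DEFAULT_ATTRIBUTES, EmptyAnalysisError, bw_scores,
                    count_choices, friedman_from_ranks, friedman_test, generate,
                    implied_ranks, mean_bw, normalized_weights,
                    preset_paper_like, rank_matrix, score_table,
                    score_table_from_counts, BWSCounts)
from qolbws.reference import published_counts

from conftest import ATTR_IDS, make_dataset, make_record


def counts_from(best, worst):
    return BWSCounts(DEFAULT_ATTRIBUTES, tuple(best), tuple(worst))


class TestCounting:
    def test_unanimous_choices(self):
        ds = make_dataset([make_record(i, "spiritual", "food") for i in range(3)])
        counts = count_choices(ds)
        assert counts.best == (3, 0, 0, 0, 0, 0)
        assert counts.worst == (0, 3, 0, 0, 0, 0)

    def test_totals_conserved_on_simulated_data(self, preset_dataset):
        counts = count_choices(preset_dataset)
        assert sum(counts.best) == sum(counts.worst) == 213

    def test_matches_per_record_brute_force(self):
        ds, _ = generate(preset_paper_like(n_respondents=1000, seed=9))
        counts = count_choices(ds)
        for j, aid in enumerate(ATTR_IDS):
            assert counts.best[j] == sum(r.best == aid for r in ds.records)
            assert counts.worst[j] == sum(r.worst == aid for r in ds.records)

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyAnalysisError):
            count_choices(make_dataset([]))


class TestScores:
    def test_published_frequency_columns(self):
        table = score_table_from_counts(published_counts())
        rows = {r.attribute_id: r for r in table.rows}
        assert [rows[a].bw for a in ATTR_IDS] == [48, 14, 45, -90, 35, -52]
        assert rows["spiritual"].mean_bw == 0.225
        assert rows["food"].mean_bw == 0.066
        assert rows["economic"].mean_bw == 0.164
        assert rows["social"].mean_bw == -0.423
        assert [rows[a].weight for a in ATTR_IDS] == [25.56, 19.26, 25.00, 0.00,
                                                      23.15, 7.04]
        assert rows["spiritual"].rank == 1
        assert rows["social"].rank == 6

    def test_bw_is_best_minus_worst(self):
        counts = counts_from((70, 10, 5, 5, 5, 5), (22, 58, 5, 5, 5, 5))
        assert bw_scores(counts)[:2] == (48, -48)

    def test_mean_rounding_and_domain(self):
        assert mean_bw(48, 213) == 0.225
        assert mean_bw(14, 213) == 0.066
        assert mean_bw(0, 10) == 0.0
        with pytest.raises(ValueError):
            mean_bw(1, 0)

    def test_weights_published_vector(self):
        w = normalized_weights([48, 14, 45, -90, 35, -52])
        assert list(w) == [25.56, 19.26, 25.00, 0.00, 23.15, 7.04]
        assert sum(w) == pytest.approx(100.01)

    def test_weights_degenerate_uniform(self):
        assert normalized_weights([3, 3, 3, 3, 3, 3]) == (16.67,) * 6

    def test_weights_two_attributes(self):
        assert normalized_weights([5, -5]) == (100.00, 0.00)

    def test_weights_need_two_attributes(self):
        with pytest.raises(ValueError):
            normalized_weights([1])

    def test_rank_tie_breaks_by_best_count_then_order(self):
        counts = counts_from((5, 9, 9, 1, 3, 3), (3, 7, 7, 9, 2, 2))
        table = score_table_from_counts(counts)
        by_rank = [r.attribute_id for r in table.by_rank()]
        # food and health tie at bw=2 with equal best counts: declared order
        assert by_rank.index("food") < by_rank.index("health")
        # economic and community tie at bw=1: both best=3, declared order
        assert by_rank.index("economic") < by_rank.index("community")

    def test_permuting_attribute_order_permutes_rows_not_values(self):
        from qolbws import AttributeSet
        perm = AttributeSet(tuple(DEFAULT_ATTRIBUTES.items[::-1]))
        counts = published_counts()
        permuted = BWSCounts(perm, counts.best[::-1], counts.worst[::-1])
        t1 = score_table_from_counts(counts)
        t2 = score_table_from_counts(permuted)
        for aid in ATTR_IDS:
            assert t1.row(aid).weight == t2.row(aid).weight
            assert t1.row(aid).rank == t2.row(aid).rank

    def test_records_and_marginal_counts_agree(self, preset_dataset):
        via_records = score_table(preset_dataset)
        via_counts = score_table_from_counts(count_choices(preset_dataset))
        assert via_records == via_counts


bw_vectors = st.lists(st.integers(-100, 100), min_size=2, max_size=8)


class TestScoreProperties:
    @given(st.lists(st.tuples(st.sampled_from(ATTR_IDS), st.sampled_from(ATTR_IDS))
                    .filter(lambda t: t[0] != t[1]), min_size=1, max_size=50))
    def test_bw_sums_to_zero(self, picks):
        ds = make_dataset([make_record(i, b, w) for i, (b, w) in enumerate(picks)])
        assert sum(bw_scores(count_choices(ds))) == 0

    @given(bw_vectors)
    def test_weights_sum_to_100_and_min_is_zero(self, bw):
        w = normalized_weights(bw)
        assert sum(w) == pytest.approx(100, abs=0.02 * len(bw))
        if len(set(bw)) > 1:
            assert min(w) == 0.0

    def test_order_equivalence_of_bw_mean_weight(self, preset_dataset):
        table = score_table(preset_dataset)
        by_bw = sorted(ATTR_IDS, key=lambda a: -table.row(a).bw)
        by_mean = sorted(ATTR_IDS, key=lambda a: -table.row(a).mean_bw)
        by_weight = sorted(ATTR_IDS, key=lambda a: -table.row(a).weight)
        assert by_bw == by_mean == by_weight


class TestImpliedRanks:
    def test_six_attribute_pattern(self):
        ranks = implied_ranks(0, 5, 6)
        assert ranks[0] == 1 and ranks[5] == 6
        assert set(ranks[1:5]) == {3.5}
        assert ranks.sum() == 21

    def test_three_attribute_middle_rank(self):
        assert list(implied_ranks(0, 2, 3)) == [1, 2, 3]

    @given(st.integers(3, 9), st.data())
    def test_rank_sum_is_triangular(self, J, data):
        best = data.draw(st.integers(0, J - 1))
        worst = data.draw(st.integers(0, J - 1).filter(lambda w: w != best))
        assert implied_ranks(best, worst, J).sum() == J * (J + 1) / 2


class TestFriedman:
    def test_unanimous_pattern_matches_closed_form(self):
        # every respondent best=spiritual worst=community: rank sums are
        # fully determined, and the tie-corrected statistic reduces to
        # 2.5 * sum(bw^2) / n for the single-task design.
        ds = make_dataset([make_record(i, "spiritual", "community")
                           for i in range(20)])
        res = friedman_test(ds)
        bw = np.array(bw_scores(count_choices(ds)))
        assert res.statistic == pytest.approx(2.5 * (bw ** 2).sum() / 20)
        assert res.df == 5

    def test_matches_scipy_oracle_on_small_fixtures(self):
        for seed in (1, 2, 3):
            ds, _ = generate(preset_paper_like(n_respondents=30, seed=seed))
            ranks = rank_matrix(ds)
            ours = friedman_from_ranks(ranks)
            oracle = friedmanchisquare(*(ranks[:, j] for j in range(ranks.shape[1])))
            assert ours.statistic == pytest.approx(oracle.statistic)
            assert ours.p_value == pytest.approx(oracle.pvalue)

    def test_row_permutation_invariance(self):
        ds, _ = generate(preset_paper_like(n_respondents=25, seed=4))
        permuted = ds.subset(ds.records[::-1])
        assert friedman_test(ds).statistic == pytest.approx(
            friedman_test(permuted).statistic)

    def test_null_mean_is_df(self):
        # uniform random best/worst: E[statistic] = J - 1 = 5
        rng = np.random.default_rng(2024)
        stats = []
        for _ in range(300):
            best = rng.integers(0, 6, size=500)
            shift = rng.integers(1, 6, size=500)
            worst = (best + shift) % 6
            ranks = np.vstack([implied_ranks(b, w, 6) for b, w in zip(best, worst)])
            stats.append(friedman_from_ranks(ranks).statistic)
        # SE of the mean of 300 chi2(5) draws is sqrt(10/300) ~ 0.18
        assert np.mean(stats) == pytest.approx(5.0, abs=3 * 0.19)

    def test_needs_three_attributes(self):
        from qolbws import AttributeSet, Dataset, DEFAULT_SCHEMA, RespondentRecord
        two = AttributeSet((("a", "A"), ("b", "B")))
        ds = Dataset(two, DEFAULT_SCHEMA, (RespondentRecord("r", "a", "b", {}),))
        with pytest.raises(ValueError):
            friedman_test(ds)
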