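"""Synthetic respondent generator: choice model, marginals, determinism."""

import dataclasses

import numpy as np
import pytest

from qolbws import (ConfigError, SegmentSpec, SimConfig, choice_shares, clean,
                    expected_shares, generate, preset_generating_order,
                    preset_paper_like, sample_choice, sample_demographics,
                    score_table)
from qolbws import reference
from qolbws.simulate import utilities_for

from conftest import ATTR_IDS


def small_config(**kw):
    defaults = dict(n_respondents=10, seed=0,
                    demographic_marginals=reference.demographic_marginals(),
                    base_utilities=(0.5, 0.1, 0.3, -0.5, 0.2, -0.6))
    defaults.update(kw)
    return SimConfig(**defaults)


class TestValidation:
    def test_bad_fields_are_all_reported(self):
        cfg = small_config(n_respondents=0, incomplete_rate=1.5,
                           base_utilities=(1.0, 2.0))
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        text = str(err.value)
        assert "n_respondents" in text
        assert "incomplete_rate" in text
        assert "base_utilities" in text

    def test_marginals_must_sum_to_one(self):
        cfg = small_config(demographic_marginals={"gender": {"female": 0.7,
                                                             "male": 0.2}})
        with pytest.raises(ConfigError, match="gender"):
            cfg.validate()

    def test_preset_is_valid(self):
        preset_paper_like().validate()


class TestSampling:
    def test_degenerate_marginal_is_deterministic(self):
        cfg = small_config(demographic_marginals={"gender": {"female": 1.0}})
        rng = np.random.default_rng(0)
        assert all(sample_demographics(cfg, rng)["gender"] == "female"
                   for _ in range(20))

    def test_marginal_law_of_large_numbers(self):
        cfg = preset_paper_like(n_respondents=10000, seed=21)
        ds, _ = generate(cfg)
        share = np.mean([r.demographic("gender") == "female" for r in ds.records])
        target = reference.DEMOGRAPHIC_COUNTS["gender"]["female"] / 217
        se = np.sqrt(target * (1 - target) / 10000)
        assert abs(share - target) < 3 * se

    def test_dominant_utility_always_wins(self):
        rng = np.random.default_rng(1)
        u = (20.0, 0.0, 0.0, 0.0, 0.0, -20.0)
        draws = [sample_choice(u, rng) for _ in range(500)]
        assert all(b == 0 and w == 5 for b, w in draws)

    def test_best_never_equals_worst(self):
        rng = np.random.default_rng(2)
        assert all(b != w for b, w in
                   (sample_choice((0.0,) * 6, rng) for _ in range(2000)))

    def test_best_shares_match_softmax_oracle(self):
        u = np.array([1.0, 0.0, -1.0, 0.0, 0.0, 0.0])
        target = np.exp(u) / np.exp(u).sum()
        rng = np.random.default_rng(3)
        n = 60000
        counts = np.zeros(6)
        for _ in range(n):
            b, _w = sample_choice(u, rng)
            counts[b] += 1
        shares = counts / n
        se = np.sqrt(target * (1 - target) / n)
        assert (np.abs(shares - target) < 3.5 * se).all()

    def test_worst_shares_match_exact_model(self):
        # empirical worst shares against the closed-form sequential model
        u = np.array([1.0, 0.5, 0.0, -0.5, -1.0, 0.0])
        _, target = choice_shares(u)
        rng = np.random.default_rng(4)
        n = 60000
        counts = np.zeros(6)
        for _ in range(n):
            _b, w = sample_choice(u, rng)
            counts[w] += 1
        shares = counts / n
        se = np.sqrt(target * (1 - target) / n)
        assert (np.abs(shares - target) < 3.5 * se).all()


class TestGenerate:
    def test_identical_seed_is_byte_identical(self, tmp_path):
        from qolbws import write_dataset
        cfg = preset_paper_like(n_respondents=100, seed=13,
                                incomplete_rate=0.05, contradictory_rate=0.02)
        paths = []
        for name in ("a.csv", "b.csv"):
            ds, _ = generate(cfg)
            write_dataset(ds, tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_records_reproducible_in_isolation(self):
        cfg = preset_paper_like(n_respondents=50, seed=17)
        ds1, _ = generate(cfg)
        ds2, _ = generate(dataclasses.replace(cfg, n_respondents=10))
        assert ds1.records[:10] == ds2.records[:10]

    def test_zero_rates_clean_removes_nothing(self):
        ds, _ = generate(preset_paper_like(n_respondents=213, seed=1))
        cleaned, report = clean(ds)
        assert report.n_valid == 213
        assert all(v == 0 for v in report.removed_by_reason.values())

    def test_corruption_labels_match_observed_damage(self):
        cfg = preset_paper_like(n_respondents=2000, seed=8,
                                incomplete_rate=0.1, contradictory_rate=0.05)
        ds, truth = generate(cfg)
        for rec, gt in zip(ds.records, truth.records):
            if gt.corruption == "incomplete":
                assert rec.worst is None
            elif gt.corruption == "contradictory":
                assert rec.worst == rec.best
            else:
                assert rec.worst == gt.choice_worst and rec.worst != rec.best

    def test_segment_shifts_applied_to_matching_respondents(self):
        cfg = small_config(segments=(SegmentSpec({"gender": "female"},
                                                 (1.0, 0, 0, 0, 0, 0)),))
        u_f = utilities_for(cfg, {"gender": "female"})
        u_m = utilities_for(cfg, {"gender": "male"})
        assert u_f[0] == u_m[0] + 1.0
        assert (u_f[1:] == u_m[1:]).all()


class TestPreset:
    def test_expected_best_counts_match_published_frequencies(self):
        best, _ = expected_shares(preset_paper_like())
        published = np.array([reference.BEST_FREQUENCIES[a] for a in ATTR_IDS])
        assert np.allclose(best * 213, published, atol=0.05)

    def test_mean_spiritual_best_count_over_seeds(self):
        """Simulated mean best count for spiritual well-being sits at its
        published frequency (the moment-matching target) within MC error."""
        counts = []
        for seed in range(120):
            ds, _ = generate(preset_paper_like(seed=seed))
            counts.append(score_table(ds).row("spiritual").best)
        se = np.sqrt(213 * 0.3286 * (1 - 0.3286) / 120)
        assert np.mean(counts) == pytest.approx(70, abs=3 * se)

    def test_generating_order_starts_at_spiritual_ends_low(self):
        order = preset_generating_order()
        assert order[0] == "spiritual"
        assert set(order[-2:]) == {"social", "community"}

    def test_estimator_consistency_in_n(self):
        # with well-separated utilities the sample B-W ordering converges
        # to the true utility ordering
        base = (1.0, 0.5, 0.0, -0.4, -0.8, -1.2)
        truth = tuple(ATTR_IDS)  # already in descending utility order
        agreement = []
        for n, seed in ((200, 31), (2000, 32), (20000, 33)):
            cfg = small_config(n_respondents=n, seed=seed, base_utilities=base)
            ds, _ = generate(cfg)
            order = tuple(r.attribute_id for r in score_table(ds).by_rank())
            agreement.append(order == truth)
        assert agreement[-1]  # exact recovery at the largest n
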