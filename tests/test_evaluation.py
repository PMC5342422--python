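"""NDCG, hypergeometric enrichment, cross-validation and group comparisons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slranker.evaluation import (
    compare_drug_sensitivity,
    cross_validate,
    enrichment_p,
    label_permuted_records,
    ndcg_at_p,
    optimize_alpha,
    relative_growth,
)
from slranker.features import build_feature_table
from slranker.io import GenePair, PairRecord, RunConfig


def brute_ndcg(rel, p, total_relevant):
    dcg = sum((2 ** r - 1) / math.log2(i + 2) for i, r in enumerate(rel[:p]))
    ideal = sum(1 / math.log2(i + 2) for i in range(min(total_relevant, p)))
    return dcg / ideal if ideal else 0.0


def brute_enrichment(n_total, m_pos, top_n, k):
    """Exhaustive draw enumeration: P(#positives in a random top-n > k)."""
    items = [1] * m_pos + [0] * (n_total - m_pos)
    draws = list(itertools.combinations(range(n_total), top_n))
    hits = sum(1 for d in draws if sum(items[i] for i in d) > k)
    return hits / len(draws)


class TestNdcg:
    def test_perfect_ranking_is_one(self):
        assert ndcg_at_p([1, 1, 1], p=3, total_relevant=3) == pytest.approx(1.0)

    def test_no_relevant_in_top_is_zero(self):
        assert ndcg_at_p([0, 0, 0, 0, 1], p=4, total_relevant=1) == 0.0

    def test_three_positives_at_ranks_2_3_8_top5(self):
        # direct evaluation of the discounted-gain formula:
        # (1/log2 3 + 1/log2 4) / (1/log2 2 + 1/log2 3 + 1/log2 4) ~ 0.5307
        rel = [0, 1, 1, 0, 0, 0, 0, 1]
        expected = (1 / math.log2(3) + 1 / math.log2(4)) / (
            1 + 1 / math.log2(3) + 1 / math.log2(4)
        )
        assert ndcg_at_p(rel, p=5, total_relevant=3) == pytest.approx(expected)
        assert expected == pytest.approx(0.530721, abs=1e-6)

    def test_ideal_truncates_at_p(self):
        # more relevant items than positions: ideal uses only p slots
        assert ndcg_at_p([1, 1], p=2, total_relevant=10) == pytest.approx(1.0)

    @given(
        rel=st.lists(st.integers(0, 1), min_size=1, max_size=30),
        p=st.integers(1, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, rel, p):
        total = sum(rel) if sum(rel) else 1
        assert ndcg_at_p(rel, p, total) == pytest.approx(brute_ndcg(rel, p, total))

    def test_promoting_a_relevant_item_never_hurts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rel = rng.integers(0, 2, size=12).tolist()
            ones = [i for i, r in enumerate(rel) if r and i > 0 and rel[i - 1] == 0]
            if not ones:
                continue
            i = ones[0]
            swapped = rel.copy()
            swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
            total = max(sum(rel), 1)
            assert ndcg_at_p(swapped, 12, total) >= ndcg_at_p(rel, 12, total) - 1e-12


class TestEnrichment:
    def test_all_positives_captured_gives_zero(self):
        assert enrichment_p(10, 3, 5, 3) == 0.0

    def test_small_case_by_hand(self):
        # N=4, M=2, n=2, k=0: 1 - C(2,0)C(2,2)/C(4,2) = 5/6
        assert enrichment_p(4, 2, 2, 0) == pytest.approx(5 / 6)

    def test_no_positives_at_all(self):
        assert enrichment_p(8, 0, 3, 0) == 0.0

    def test_ge_tail_includes_k(self):
        printed = enrichment_p(20, 5, 5, 2, tail="printed")
        ge = enrichment_p(20, 5, 5, 2, tail="ge")
        assert ge > printed

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            enrichment_p(5, 6, 2, 1)
        with pytest.raises(ValueError):
            enrichment_p(5, 2, 2, 3)

    def test_exhaustive_enumeration_small(self):
        for n_total in (4, 6, 8):
            for m_pos in range(n_total + 1):
                for top_n in range(1, n_total + 1):
                    for k in range(min(m_pos, top_n) + 1):
                        assert enrichment_p(n_total, m_pos, top_n, k) == pytest.approx(
                            brute_enrichment(n_total, m_pos, top_n, k), abs=1e-12
                        )


def _feature_records(n_pos=10, n_cand=40, seed=0, signal=True):
    """Records with separated (signal) or identical (no-signal) feature triples."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_pos):
        feats = rng.normal([0.8, 0.8, 0.5], 0.05) if signal else np.full(3, 0.5)
        records.append(
            PairRecord(
                pair=GenePair.of(f"P{i:02d}", f"Q{i:02d}"), label="positive",
                coverage=1, driver_score=1, centrality=1,
                normalized=tuple(np.clip(feats, 0, 1)),
            )
        )
    for i in range(n_cand):
        feats = rng.normal([0.2, 0.2, 0.1], 0.05) if signal else np.full(3, 0.5)
        records.append(
            PairRecord(
                pair=GenePair.of(f"A{i:02d}", f"B{i:02d}"), label="candidate",
                coverage=0, driver_score=0, centrality=0,
                normalized=tuple(np.clip(feats, 0, 1)),
            )
        )
    return records


class TestCrossValidate:
    def test_fold_bookkeeping(self):
        cfg = RunConfig(cv_folds=5, cv_shuffles=10, rng_seed=1)
        res = cross_validate(_feature_records(), cfg, alpha=0.5)
        assert len(res.folds) == 50
        assert all(len(f.heldout_ranks) == 2 for f in res.folds)  # 10 positives / 5 folds
        assert all(f.p == 2 for f in res.folds)

    def test_partition_covers_every_positive_once_per_shuffle(self):
        cfg = RunConfig(cv_folds=5, cv_shuffles=3, rng_seed=2)
        records = _feature_records(n_pos=11)
        from slranker.evaluation import _CvEngine

        engine = _CvEngine(records, cfg)
        for partition in engine.partitions:
            allidx = np.concatenate(partition)
            assert sorted(allidx.tolist()) == sorted(engine.pos_idx.tolist())

    def test_identical_seed_identical_result(self):
        cfg = RunConfig(rng_seed=3)
        r1 = cross_validate(_feature_records(), cfg, alpha=0.7)
        r2 = cross_validate(_feature_records(), cfg, alpha=0.7)
        assert r1 == r2

    def test_signal_beats_label_permuted_baseline(self):
        cfg = RunConfig(cv_shuffles=3, rng_seed=4)
        records = _feature_records(seed=4)
        real = cross_validate(records, cfg, alpha=0.8)
        permuted = cross_validate(label_permuted_records(records, 99), cfg, alpha=0.8)
        assert real.mean_ndcg > permuted.mean_ndcg

    def test_too_few_positives_rejected(self):
        cfg = RunConfig(cv_folds=5)
        with pytest.raises(ValueError, match="positives"):
            cross_validate(_feature_records(n_pos=3), cfg, alpha=0.5)


class TestOptimizeAlpha:
    def test_singleton_grid(self):
        cfg = RunConfig(alpha_grid=(0.0,), cv_shuffles=2, rng_seed=5)
        best, results = optimize_alpha(_feature_records(), cfg)
        assert best == 0.0 and len(results) == 1

    def test_tie_returns_smallest_alpha(self):
        # identical feature vectors: ranking (and NDCG) invariant across alphas
        cfg = RunConfig(alpha_grid=(0.2, 0.6), cv_shuffles=2, rng_seed=6)
        best, results = optimize_alpha(_feature_records(signal=False), cfg)
        assert results[0].mean_ndcg == pytest.approx(results[1].mean_ndcg)
        assert best == 0.2

    def test_returns_grid_argmax(self):
        cfg = RunConfig(alpha_grid=(0.0, 0.3, 0.6, 0.9), cv_shuffles=2, rng_seed=7)
        best, results = optimize_alpha(_feature_records(seed=7), cfg)
        by_alpha = {r.alpha: r.mean_ndcg for r in results}
        assert by_alpha[best] == max(by_alpha.values())


class TestDrugSensitivity:
    def test_identical_groups_half(self):
        assert compare_drug_sensitivity([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_shifted_mutant_group_significant(self):
        rng = np.random.default_rng(8)
        wt = rng.normal(0, 1, size=10)
        mut = rng.normal(3, 1, size=10)
        assert compare_drug_sensitivity(mut, wt, higher_is_sensitive=True) < 0.01

    def test_orientation_flag_flips_tail(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        p_hi = compare_drug_sensitivity(a, b, higher_is_sensitive=True)
        p_lo = compare_drug_sensitivity(a, b, higher_is_sensitive=False)
        assert p_hi + p_lo == pytest.approx(1.0)

    def test_constant_equal_groups_half(self):
        assert compare_drug_sensitivity([2, 2, 2], [2, 2, 2]) == 0.5

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_drug_sensitivity([1], [1, 2])


class TestRelativeGrowth:
    def test_ratio(self):
        assert relative_growth(0.5, 1.0) == 0.5
        assert relative_growth(1.3, 1.3) == 1.0

    def test_nonpositive_placebo_rejected(self):
        with pytest.raises(ValueError):
            relative_growth(0.5, 0.0)
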