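"""Ranking, selection, confusion metrics, exact CIs, overlap, and coverage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plauscheck import (
    AnomalyScores,
    SelectionSample,
    TruthLabels,
    binary_labels_at_k,
    cross_rank_coverage,
    distinct_values_table,
    exact_binomial_ci,
    max_ci_width,
    overlap_counts,
    precision_at,
    precision_curve,
    rank_records,
    ranking_curves,
    roc_auc,
    select_random,
    select_top,
    sensitivity_specificity,
    stratum_table,
)
from plauscheck.evaluation import LabelingError, MetricUndefinedError
from conftest import random_table


def low_scores(values, ids=None) -> AnomalyScores:
    ids = ids if ids is not None else range(len(values))
    return AnomalyScores(pd.Series(values, index=list(ids)), "low", "test")


def random_ranking_and_truth(rng, n, p=0.3):
    scores = AnomalyScores(
        pd.Series(rng.random(n), index=range(n)), "high", "test"
    )
    truth = TruthLabels(pd.Series(rng.random(n) < p, index=range(n)))
    return rank_records(scores), truth


class TestRanking:
    def test_toy_fpof_scores_rank_with_row_id_tie_break(self):
        ranking = rank_records(low_scores([1 / 3, 1 / 4, 1 / 4]))
        assert ranking.order.tolist() == [1, 2, 0]
        assert ranking.ranks.to_dict() == {1: 1, 2: 2, 0: 3}

    def test_high_orientation_identity_on_decreasing_scores(self):
        scores = AnomalyScores(pd.Series([9.0, 5.0, 1.0]), "high", "t")
        assert rank_records(scores).order.tolist() == [0, 1, 2]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.random(40), index=range(40))
        base = rank_records(AnomalyScores(vals, "low", "t"))
        perm = vals.sample(frac=1, random_state=1)
        other = rank_records(AnomalyScores(perm, "low", "t"))
        assert (base.order == other.order).all()

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_records(low_scores([0.1, np.nan]))


class TestSelection:
    def test_top_n_prefix_nesting_and_bounds(self):
        ranking = rank_records(low_scores(np.arange(10)[::-1] / 10.0))
        full = select_top(ranking, 10)
        assert full.n == 10
        single = select_top(ranking, 1)
        assert single.row_ids.tolist() == [ranking.order[0]]
        for n in range(1, 10):
            assert set(select_top(ranking, n).row_ids) <= set(
                select_top(ranking, n + 1).row_ids
            )
        with pytest.raises(ValueError):
            select_top(ranking, 11)

    def test_random_selection_reproducible_and_uniform(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, 6, 2)
        a = select_random(table, 3, seed=5)
        b = select_random(table, 3, seed=5)
        assert (a.row_ids == b.row_ids).all()
        hits = np.zeros(6)
        n_draws = 2000
        for s in range(n_draws):
            for r in select_random(table, 3, seed=s).row_ids:
                hits[r] += 1
        freq = hits / n_draws
        se = np.sqrt(0.5 * 0.5 / n_draws)
        assert (np.abs(freq - 0.5) <= 3 * se).all()


class TestPrecision:
    def test_degenerate_all_and_none(self):
        sample = SelectionSample("t", np.arange(4))
        all_bad = TruthLabels(pd.Series(True, index=range(4)))
        none_bad = TruthLabels(pd.Series(False, index=range(4)))
        assert precision_at(sample, all_bad) == 1.0
        assert precision_at(sample, none_bad) == 0.0

    def test_23_of_300_is_8_percent(self):
        sample = SelectionSample("t", np.arange(300))
        truth = TruthLabels(pd.Series([True] * 23 + [False] * 277, index=range(300)))
        assert precision_at(sample, truth) == pytest.approx(23 / 300)

    def test_uncovered_row_raises(self):
        sample = SelectionSample("t", np.arange(3))
        truth = TruthLabels(pd.Series([True], index=[0]))
        with pytest.raises(LabelingError):
            precision_at(sample, truth)

    def test_curve_closed_forms_and_brute_recount(self):
        # perfect ranking: all positives first
        ranking = rank_records(low_scores(np.arange(10) / 10.0))
        truth = TruthLabels(pd.Series([True] * 3 + [False] * 7, index=range(10)))
        curve = dict(precision_curve(ranking, truth, 10))
        for n in range(1, 4):
            assert curve[n] == 1.0
        for n in range(4, 11):
            assert curve[n] == pytest.approx(3 / n)
        # inverted ranking: zero until positives appear
        inv = rank_records(low_scores(np.arange(10)[::-1] / 10.0))
        curve_inv = dict(precision_curve(inv, truth, 10))
        for n in range(1, 8):
            assert curve_inv[n] == 0.0
        # random fixture vs per-n recount
        rng = np.random.default_rng(12)
        ranking, truth = random_ranking_and_truth(rng, 30)
        for n, p in precision_curve(ranking, truth, 30):
            manual = truth.lookup(ranking.order[:n]).sum() / n
            assert p == pytest.approx(manual)


class TestConfusion:
    def test_binary_labels_boundaries_and_prefix_consistency(self):
        ranking = rank_records(low_scores(np.arange(6) / 6.0))
        assert not binary_labels_at_k(ranking, 0).any()
        assert binary_labels_at_k(ranking, 6).all()
        for k in range(6):
            a = binary_labels_at_k(ranking, k)
            b = binary_labels_at_k(ranking, k + 1)
            assert int((a != b).sum()) == 1

    def test_perfect_and_null_predictions(self):
        truth = TruthLabels(pd.Series([True, True, False, False], index=range(4)))
        perfect = pd.Series([True, True, False, False], index=range(4))
        assert sensitivity_specificity(perfect, truth) == (1.0, 1.0)
        nothing = pd.Series(False, index=range(4))
        assert sensitivity_specificity(nothing, truth) == (0.0, 1.0)

    def test_single_class_raises(self):
        truth = TruthLabels(pd.Series(True, index=range(3)))
        pred = pd.Series(True, index=range(3))
        with pytest.raises(MetricUndefinedError):
            sensitivity_specificity(pred, truth)

    def test_matches_confusion_matrix_oracle_and_integer_identity(self):
        rng = np.random.default_rng(3)
        ranking, truth = random_ranking_and_truth(rng, 50)
        P = int(truth.implausible.sum())
        N = 50 - P
        prev_sens, prev_spec = -1.0, 2.0
        for k in range(0, 51):
            pred = binary_labels_at_k(ranking, k)
            sens, spec = sensitivity_specificity(pred, truth)
            actual = truth.lookup(pred.index)
            tp = int((pred.to_numpy() & actual).sum())
            fp = int((pred.to_numpy() & ~actual).sum())
            tn = int((~pred.to_numpy() & ~actual).sum())
            fn = int((~pred.to_numpy() & actual).sum())
            assert sens == pytest.approx(tp / P)
            assert spec == pytest.approx(tn / N)
            # TP identity with precision@k
            if k:
                sample = SelectionSample("t", ranking.order[:k])
                assert precision_at(sample, truth) * k == pytest.approx(tp)
            # monotone in k
            assert sens >= prev_sens - 1e-12
            assert spec <= prev_spec + 1e-12
            prev_sens, prev_spec = sens, spec


class TestRankingCurves:
    def test_roc_endpoints_and_perfect_area(self):
        ranking = rank_records(low_scores(np.arange(10) / 10.0))
        truth = TruthLabels(pd.Series([True] * 3 + [False] * 7, index=range(10)))
        roc, ps = ranking_curves(ranking, truth)
        assert tuple(roc[0, 1:]) == (0.0, 0.0)
        assert tuple(roc[-1, 1:]) == (1.0, 1.0)
        assert (0.0, 1.0) in {tuple(r) for r in roc[:, 1:]}
        assert roc_auc(roc) == pytest.approx(1.0)
        assert (np.diff(roc[:, 2]) >= 0).all()

    def test_constant_scores_follow_chance_diagonal(self):
        scores = low_scores(np.zeros(40))
        rng = np.random.default_rng(8)
        truth = TruthLabels(pd.Series(rng.random(40) < 0.5, index=range(40)))
        roc, _ = ranking_curves(rank_records(scores), truth)
        assert abs(roc_auc(roc) - 0.5) < 0.15

    def test_points_match_per_k_recomputation(self):
        rng = np.random.default_rng(31)
        ranking, truth = random_ranking_and_truth(rng, 25)
        roc, ps = ranking_curves(ranking, truth)
        for k in range(0, 26):
            pred = binary_labels_at_k(ranking, k)
            sens, spec = sensitivity_specificity(pred, truth)
            assert roc[k, 1] == pytest.approx(1 - spec)
            assert roc[k, 2] == pytest.approx(sens)
            if k:
                assert ps[k - 1, 1] == pytest.approx(sens)
                assert ps[k - 1, 2] == pytest.approx(
                    precision_at(SelectionSample("t", ranking.order[:k]), truth)
                )


def ci_tail_sum_oracle(k: int, n: int, confidence: float) -> tuple[float, float]:
    """Independent Clopper–Pearson bounds by root-finding on binomial tails."""
    from scipy.optimize import brentq

    alpha = 1 - confidence
    if k == 0:
        lower = 0.0
    else:
        lower = brentq(
            lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13,
        )
    if k == n:
        upper = 1.0
    else:
        upper = brentq(
            lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13,
        )
    return lower, upper


class TestExactBinomialCI:
    def test_boundary_closed_forms(self):
        lo, _ = exact_binomial_ci(0, 50)
        _, hi = exact_binomial_ci(50, 50)
        assert lo == 0.0 and hi == 1.0

    def test_interval_contains_point_estimate_and_is_symmetric(self):
        for k in (0, 3, 17, 40):
            lo, hi = exact_binomial_ci(k, 40)
            assert lo <= k / 40 <= hi
            lo2, hi2 = exact_binomial_ci(40 - k, 40)
            assert hi - lo == pytest.approx(hi2 - lo2, abs=1e-12)

    def test_matches_tail_sum_inversion_oracle(self):
        for k, n in ((23, 300), (0, 10), (10, 10), (5, 17)):
            got = exact_binomial_ci(k, n, 0.95)
            want = ci_tail_sum_oracle(k, n, 0.95)
            assert got == pytest.approx(want, abs=1e-9)

    def test_max_width_at_300_bounds_the_design(self):
        assert max_ci_width(300, 0.95) <= 0.12


class TestOverlapStrataDiversityCoverage:
    def test_overlap_disjoint_identical_and_conservation(self):
        a = SelectionSample("a", np.arange(0, 5))
        b = SelectionSample("b", np.arange(5, 10))
        rep = overlap_counts([a, b])
        assert rep.pairwise[("a", "b")] == 0
        assert rep.union_size == 10
        same = overlap_counts([a, SelectionSample("b", np.arange(0, 5))])
        assert same.pairwise[("a", "b")] == 5
        rng = np.random.default_rng(2)
        samples = [
            SelectionSample(f"s{i}", rng.choice(30, size=12, replace=False))
            for i in range(3)
        ]
        rep = overlap_counts(samples)
        assert rep.total_selected == 36
        union = set()
        for s in samples:
            union |= set(s.row_ids.tolist())
        assert rep.union_size == len(union)

    def test_stratum_table_shares_and_groupby_oracle(self):
        ids = np.arange(10)
        truth = TruthLabels(pd.Series([True, False] * 5, index=ids))
        strata = pd.Series(["x"] * 10, index=ids)
        df = stratum_table([SelectionSample("s", ids)], truth, strata)
        all_row = df[(df["sample"] == "s") & (df["stratum"] == "all")].iloc[0]
        x_row = df[(df["sample"] == "s") & (df["stratum"] == "x")].iloc[0]
        assert all_row["share"] == 1.0 and x_row["share"] == 1.0
        assert x_row["n_implausible"] == 5

        # registry-shaped counts: 11573/6995/2536 of 21104 give 54/34/12%
        counts = {"breast": 11573, "colorectal": 6995, "prostate": 2536}
        ids = np.arange(21104)
        labels = np.concatenate(
            [np.full(c, s) for s, c in counts.items()]
        )
        strata = pd.Series(labels, index=ids)
        truth = TruthLabels(pd.Series(False, index=ids))
        df = stratum_table([SelectionSample("full", ids)], truth, strata)
        shares = df.set_index("stratum")["share"]
        for s, c in counts.items():
            assert shares[s] == pytest.approx(c / 21104, abs=1e-12)
        # integer display shares land on the familiar 54/34/12 split
        assert abs(shares["breast"] * 100 - 54) <= 1
        assert abs(shares["colorectal"] * 100 - 34) <= 1
        assert abs(shares["prostate"] * 100 - 12) <= 1

    def test_distinct_values_single_record_and_toy(self, toy_table):
        single = toy_table.subset([0])
        assert (distinct_values_table(single) == 1).all()
        counts = distinct_values_table(toy_table)
        assert counts["sex"] == 2 and counts["localization"] == 2

    def test_cross_rank_coverage_extremes_and_oracle(self):
        ranking = rank_records(low_scores(np.arange(12) / 12.0))
        assert cross_rank_coverage([ranking.order[0]], ranking) == 1
        assert cross_rank_coverage(ranking.order, ranking) == 12
        rng = np.random.default_rng(6)
        targets = rng.choice(12, size=4, replace=False)
        expected = max(ranking.ranks[t] for t in targets)
        assert cross_rank_coverage(targets, ranking) == expected
        with pytest.raises(ValueError):
            cross_rank_coverage([99], ranking)
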