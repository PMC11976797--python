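import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vepbench.metrics import (
    METRIC_AUC,
    METRIC_KENDALL,
    METRIC_PEARSON,
    MetricEstimate,
    UndefinedMetricError,
    auc,
    bootstrap_indices,
    bootstrap_metric,
    compare_binomial,
    evaluate_predictors,
    head_to_head,
    kendall_tau,
    pairwise_correlation_matrix,
    rank_predictors,
)
from vepbench.metrics import pearson
from vepbench.predictions import PredictionSet


def auc_oracle(labels, scores):
    """Exhaustive pairwise concordance with half credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == "LoF"]
    neg = [s for l, s in zip(labels, scores) if l == "WT-like"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def tau_oracle(x, y):
    """Brute-force tau-b over all pairs."""
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (concordant - discordant) / denom


class TestPointMetrics:
    def test_pearson_perfect(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_pearson_inverted(self):
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pearson_zero_variance(self):
        with pytest.raises(UndefinedMetricError):
            pearson([1, 2, 3], [5, 5, 5])

    def test_tau_perfect(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_tau_one_discordant_pair(self):
        assert kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)

    def test_tau_all_tied(self):
        with pytest.raises(UndefinedMetricError):
            kendall_tau([1, 2, 3], [7, 7, 7])

    def test_auc_perfect(self):
        assert auc(["LoF", "LoF", "WT-like"], [2, 3, 1]) == 1.0

    def test_auc_inverted(self):
        assert auc(["LoF", "LoF", "WT-like"], [1, 2, 3]) == 0.0

    def test_auc_hand_computed(self):
        labels = ["LoF", "WT-like", "LoF", "WT-like"]
        assert auc(labels, [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_auc_single_class(self):
        with pytest.raises(UndefinedMetricError):
            auc(["LoF", "LoF"], [1, 2])

    @given(
        st.lists(st.sampled_from(["LoF", "WT-like"]), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=200)
    def test_auc_matches_oracle(self, labels, data):
        if len(set(labels)) < 2:
            return
        scores = data.draw(
            st.lists(
                st.integers(0, 4), min_size=len(labels), max_size=len(labels)
            )
        )
        assert auc(labels, scores) == pytest.approx(auc_oracle(labels, scores))

    @given(st.integers(3, 8), st.data())
    @settings(max_examples=200)
    def test_tau_matches_oracle(self, n, data):
        x = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert kendall_tau(x, y) == pytest.approx(tau_oracle(x, y))

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = ["LoF"] * 5 + ["WT-like"] * 5
        scores = rng.normal(size=10)
        base = auc(labels, scores)
        assert auc(labels, np.exp(scores)) == pytest.approx(base)
        assert auc(labels, 3 * scores + 7) == pytest.approx(base)


class TestBootstrap:
    def test_perfect_predictor_degenerate_ci(self, rng):
        truth = rng.normal(size=15)
        est = bootstrap_metric(METRIC_PEARSON, truth, truth, n_boot=100, seed=0)
        assert est.point == pytest.approx(1.0)
        assert est.ci90 == (pytest.approx(1.0), pytest.approx(1.0))
        assert np.allclose(est.draws, 1.0)

    def test_stratified_counts_preserved(self, rng):
        labels = np.array(["LoF"] * 15 + ["WT-like"] * 13)
        idx = bootstrap_indices(28, 500, rng, labels=labels, stratified=True)
        for sample in idx:
            resampled = labels[sample]
            assert (resampled == "LoF").sum() == 15
            assert (resampled == "WT-like").sum() == 13

    def test_draw_count_and_ci_shape(self, rng):
        truth = rng.normal(size=20)
        pred = truth + rng.normal(0, 0.5, size=20)
        est = bootstrap_metric(METRIC_KENDALL, truth, pred, n_boot=250, seed=1)
        assert est.n_boot == 250
        assert est.ci90[0] <= np.median(est.draws) <= est.ci90[1]

    def test_seed_reproducibility(self, rng):
        truth = rng.normal(size=20)
        pred = truth + rng.normal(0, 0.5, size=20)
        a = bootstrap_metric(METRIC_PEARSON, truth, pred, n_boot=100, seed=42)
        b = bootstrap_metric(METRIC_PEARSON, truth, pred, n_boot=100, seed=42)
        assert np.array_equal(a.draws, b.draws)
        assert a.ci90 == b.ci90

    def test_ci_width_shrinks_with_n(self):
        # stochastic invariant: check mean width over repeated draws
        rng = np.random.default_rng(3)
        mean_widths = []
        for n in (10, 40, 160):
            widths = []
            for rep in range(15):
                truth = rng.normal(size=n)
                pred = truth + rng.normal(0, 0.8, size=n)
                est = bootstrap_metric(
                    METRIC_PEARSON, truth, pred, n_boot=200, seed=5 + rep
                )
                widths.append(est.ci90[1] - est.ci90[0])
            mean_widths.append(np.mean(widths))
        assert mean_widths[0] > mean_widths[1] > mean_widths[2]

    def test_gauss95_symmetric_about_point(self, rng):
        truth = rng.normal(size=20)
        labels = ["LoF"] * 10 + ["WT-like"] * 10
        pred = -truth + rng.normal(0, 0.5, size=20)
        est = bootstrap_metric(
            METRIC_AUC, None, pred, labels=labels, n_boot=200, seed=2
        )
        lo, hi = est.gauss95
        assert (lo + hi) / 2 == pytest.approx(est.point)


class TestCompareBinomial:
    def test_identical_draws(self):
        a = np.ones(100)
        wins, p = compare_binomial(a, a)
        assert wins == 0 and p == 1.0

    def test_all_wins_closed_form(self):
        wins, p = compare_binomial(np.ones(1000), np.zeros(1000))
        assert wins == 1000
        assert p == pytest.approx(0.5**1000, rel=1e-9)

    def test_extreme_p_representable(self):
        wins, p = compare_binomial(np.ones(1000), np.zeros(1000))
        assert 0 < p < 1e-300

    def test_antisymmetry(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        wins_ab, _ = compare_binomial(a, b)
        wins_ba, _ = compare_binomial(b, a)
        ties = int(np.sum(a == b))
        assert wins_ab + wins_ba + ties == 500

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            compare_binomial(np.ones(10), np.ones(11))

    def test_exact_tail_small_case(self):
        # n=4, wins=3: P(X>=3) = (4+1)/16
        wins, p = compare_binomial(
            np.array([1, 1, 1, 0.0]), np.array([0, 0, 0, 1.0])
        )
        assert wins == 3
        assert p == pytest.approx(5 / 16)


class TestRanking:
    def _estimates(self, table):
        return {
            name: {m: v for m, v in zip((METRIC_PEARSON, METRIC_KENDALL, METRIC_AUC), vals)}
            for name, vals in table.items()
        }

    def test_single_predictor(self):
        res = rank_predictors(self._estimates({"only": (0.5, 0.4, 0.9)}))
        assert res.order == ("only",)
        assert (res.per_metric_ranks.loc["only"] == 1).all()

    def test_tied_triplets(self):
        res = rank_predictors(
            self._estimates({"a": (0.5, 0.4, 0.9), "b": (0.5, 0.4, 0.9)})
        )
        assert res.avg_rank["a"] == res.avg_rank["b"] == 1.5

    def test_ordering(self):
        res = rank_predictors(
            self._estimates(
                {"worst": (0.1, 0.1, 0.5), "best": (0.9, 0.8, 0.99), "mid": (0.5, 0.4, 0.8)}
            )
        )
        assert res.order == ("best", "mid", "worst")

    def test_two_stage_picks_team_best(self):
        est = self._estimates(
            {
                "a1": (0.9, 0.8, 0.95),
                "a2": (0.1, 0.1, 0.5),
                "b1": (0.5, 0.4, 0.8),
            }
        )
        teams = {"a1": "alpha", "a2": "alpha", "b1": "beta"}
        res = rank_predictors(est, two_stage=True, teams=teams)
        assert res.team_best == {"alpha": "a1", "beta": "b1"}
        assert res.order == ("a1", "b1")

    def test_ranks_are_permutation(self):
        est = self._estimates(
            {f"p{i}": (0.1 * i, 0.05 * i, 0.5 + 0.04 * i) for i in range(6)}
        )
        res = rank_predictors(est)
        for m in res.per_metric_ranks.columns:
            assert sorted(res.per_metric_ranks[m]) == list(range(1, 7))


class TestEvaluateAndMatrices:
    def test_paired_draws_share_indices(self, rng):
        truth = {f"v{i}": float(x) for i, x in enumerate(rng.normal(1, 0.5, 20))}
        labels = {v: ("LoF" if t < 0.6 else "WT-like") for v, t in truth.items()}
        if len(set(labels.values())) < 2:
            pytest.skip("degenerate labels")
        p1 = PredictionSet("one", "activity", dict(truth))
        p2 = PredictionSet("two", "activity", dict(truth))
        res = evaluate_predictors([p1, p2], truth, labels, list(truth), n_boot=50, seed=9)
        for m in (METRIC_PEARSON, METRIC_KENDALL, METRIC_AUC):
            assert np.array_equal(res["one"][m].draws, res["two"][m].draws)

    def test_head_to_head_diag_nan(self, rng):
        truth = {f"v{i}": float(x) for i, x in enumerate(rng.normal(1, 0.5, 12))}
        labels = {v: ("LoF" if t < 1.0 else "WT-like") for v, t in truth.items()}
        noisy = {v: t + rng.normal(0, 0.3) for v, t in truth.items()}
        res = evaluate_predictors(
            [
                PredictionSet("exact", "activity", dict(truth)),
                PredictionSet("noisy", "activity", noisy),
            ],
            truth, labels, list(truth), n_boot=50, seed=4,
        )
        mat = head_to_head(res, METRIC_PEARSON)
        assert np.isnan(mat.loc["exact", "exact"])
        assert mat.loc["exact", "noisy"] < mat.loc["noisy", "exact"]

    def test_pairwise_matrix_properties(self, rng):
        variants = [f"v{i}" for i in range(10)]
        truth = {v: float(x) for v, x in zip(variants, rng.normal(size=10))}
        same = {"a": dict(truth), "b": dict(truth)}
        mat = pairwise_correlation_matrix(same, truth, variants)
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert mat.loc["a", "a"] == pytest.approx(1.0)  # equals truth
        noisy = {v: t + rng.normal(0, 0.5) for v, t in truth.items()}
        views = {"a": dict(truth), "c": noisy}
        mat2 = pairwise_correlation_matrix(views, truth, variants, METRIC_KENDALL)
        pd.testing.assert_frame_equal(mat2, mat2.T)
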