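"""Evaluation metrics with paired bootstrap uncertainty and ranking.

Three metrics are computed per predictor: Pearson correlation and Kendall
tau-b on the activity scale (regression view), and ROC AUC on the risk
scale (classification view) with LoF as the positive class. Uncertainty
comes from 1000 bootstrap resamples of the evaluation set — stratified by
class for AUC (preserving the LoF / WT-like counts), plain resampling for
the correlation metrics. All predictors are evaluated on the *same*
bootstrap index sets per metric family so that the per-sample win counts
feeding the one-sided binomial comparison are paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from vepbench._rng import substream
from vepbench.assay import LOF
from vepbench.predictions import (
    PredictionSet,
    classification_view,
    impute_missing,
    regression_view,
)

METRIC_PEARSON = "pearson"
METRIC_KENDALL = "kendall_tau"
METRIC_AUC = "auc"
METRICS = (METRIC_PEARSON, METRIC_KENDALL, METRIC_AUC)

DEFAULT_N_BOOT = 1000
_MAX_REDRAWS = 100


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (zero variance, single class)."""


def pearson(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Product-moment correlation; requires >= 3 pairs and nonzero variance."""
    x = np.asarray(truth, dtype=float)
    y = np.asarray(pred, dtype=float)
    if x.size < 3:
        raise UndefinedMetricError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("zero variance on one side")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Kendall rank correlation with tie correction (tau-b)."""
    x = np.asarray(truth, dtype=float)
    y = np.asarray(pred, dtype=float)
    if x.size < 3:
        raise UndefinedMetricError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("all values tied on one side")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def auc(labels: Sequence[str], risk_scores: Sequence[float]) -> float:
    """Area under the ROC curve with LoF as positive; ties get half credit.

    Equals the Mann-Whitney probability that a random LoF variant receives
    a higher risk score than a random WT-like variant.
    """
    y = np.asarray([1 if lab == LOF else 0 for lab in labels])
    if y.min() == y.max():
        raise UndefinedMetricError("single-class input")
    return float(roc_auc_score(y, np.asarray(risk_scores, dtype=float)))


_METRIC_FNS: dict[str, Callable] = {
    METRIC_PEARSON: pearson,
    METRIC_KENDALL: kendall_tau,
    METRIC_AUC: auc,
}


@dataclass(frozen=True)
class MetricEstimate:
    """Point value of a metric plus its bootstrap distribution."""

    metric: str
    point: float
    ci90: tuple[float, float]
    gauss95: tuple[float, float]
    draws: np.ndarray

    @property
    def n_boot(self) -> int:
        return len(self.draws)


def bootstrap_indices(
    n: int,
    n_boot: int,
    rng: np.random.Generator,
    *,
    labels: Sequence[str] | None = None,
    stratified: bool = False,
) -> np.ndarray:
    """(n_boot, n) resample index sets, optionally stratified by label.

    Stratified sampling resamples with replacement within each class, so
    every bootstrap set preserves the original class counts.
    """
    if not stratified:
        return rng.integers(0, n, size=(n_boot, n))
    if labels is None:
        raise ValueError("stratified sampling requires labels")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    out = np.empty((n_boot, n), dtype=np.int64)
    col = 0
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        out[:, col : col + idx.size] = rng.choice(idx, size=(n_boot, idx.size))
        col += idx.size
    return out


def _metric_on_sample(
    metric: str,
    idx: np.ndarray,
    truth: np.ndarray,
    pred: np.ndarray,
    labels: np.ndarray | None,
) -> float:
    if metric == METRIC_AUC:
        return auc(labels[idx], pred[idx])
    return _METRIC_FNS[metric](truth[idx], pred[idx])


def bootstrap_metric(
    metric: str,
    truth: Sequence[float] | None,
    pred: Sequence[float],
    labels: Sequence[str] | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    stratified: bool | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    indices: np.ndarray | None = None,
) -> MetricEstimate:
    """Point estimate plus bootstrap CI for one metric on one predictor.

    ``stratified`` defaults to True for AUC and False otherwise. A sample
    on which the metric is undefined is redrawn (up to 100 times) rather
    than propagating NaN. Pass ``indices`` to share resamples across
    predictors (paired bootstrap).
    """
    if metric not in _METRIC_FNS:
        raise ValueError(f"unknown metric {metric!r}")
    if stratified is None:
        stratified = metric == METRIC_AUC
    pred_arr = np.asarray(pred, dtype=float)
    truth_arr = None if truth is None else np.asarray(truth, dtype=float)
    labels_arr = None if labels is None else np.asarray(labels)
    if metric == METRIC_AUC and labels_arr is None:
        raise ValueError("AUC requires labels")
    n = len(pred_arr)
    if rng is None:
        rng = np.random.default_rng(seed)
    if indices is None:
        indices = bootstrap_indices(
            n, n_boot, rng, labels=labels_arr, stratified=stratified
        )
    point = _metric_on_sample(metric, np.arange(n), truth_arr, pred_arr, labels_arr)
    draws = np.empty(len(indices))
    for i, idx in enumerate(indices):
        for attempt in range(_MAX_REDRAWS + 1):
            try:
                draws[i] = _metric_on_sample(metric, idx, truth_arr, pred_arr, labels_arr)
                break
            except UndefinedMetricError:
                if attempt == _MAX_REDRAWS:
                    raise UndefinedMetricError(
                        f"{metric}: bootstrap sample degenerate after "
                        f"{_MAX_REDRAWS} redraws"
                    ) from None
                idx = bootstrap_indices(
                    n, 1, rng, labels=labels_arr, stratified=stratified
                )[0]
    lo, hi = np.percentile(draws, [5, 95])
    sd = float(draws.std(ddof=1)) if len(draws) > 1 else 0.0
    return MetricEstimate(
        metric=metric,
        point=float(point),
        ci90=(float(lo), float(hi)),
        gauss95=(float(point - 1.96 * sd), float(point + 1.96 * sd)),
        draws=draws,
    )


def evaluate_predictors(
    prediction_sets: Sequence[PredictionSet],
    truth: Mapping[str, float],
    labels: Mapping[str, str],
    eval_variants: Sequence[str],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> dict[str, dict[str, MetricEstimate]]:
    """Impute, transform and score every predictor on a common variant set.

    Bootstrap index sets are generated once per metric family (plain
    resampling for the correlation metrics, stratified for AUC) and shared
    by all predictors, so draws are paired across predictors.
    """
    order = list(eval_variants)
    t = np.array([truth[v] for v in order])
    lab = np.array([labels[v] for v in order])
    n = len(order)
    reg_rng = substream(seed, "bootstrap/regression")
    cls_rng = substream(seed, "bootstrap/classification")
    reg_idx = bootstrap_indices(n, n_boot, reg_rng)
    cls_idx = bootstrap_indices(n, n_boot, cls_rng, labels=lab, stratified=True)
    results: dict[str, dict[str, MetricEstimate]] = {}
    for pset in prediction_sets:
        complete = impute_missing(pset, order)
        reg = regression_view(complete)
        cls = classification_view(complete)
        reg_scores = np.array([reg[v] for v in order])
        cls_scores = np.array([cls[v] for v in order])
        results[pset.predictor] = {
            METRIC_PEARSON: bootstrap_metric(
                METRIC_PEARSON, t, reg_scores, rng=reg_rng, indices=reg_idx
            ),
            METRIC_KENDALL: bootstrap_metric(
                METRIC_KENDALL, t, reg_scores, rng=reg_rng, indices=reg_idx
            ),
            METRIC_AUC: bootstrap_metric(
                METRIC_AUC, None, cls_scores, labels=lab, rng=cls_rng, indices=cls_idx
            ),
        }
    return results


@dataclass(frozen=True)
class RankingResult:
    """Per-metric ranks, average rank and final order (1 = best)."""

    per_metric_ranks: pd.DataFrame
    avg_rank: pd.Series
    order: tuple[str, ...]
    team_best: Mapping[str, str] | None = None


def _points(estimates: Mapping[str, Mapping[str, object]]) -> pd.DataFrame:
    rows = {}
    for name, metrics in estimates.items():
        rows[name] = {
            m: (e.point if isinstance(e, MetricEstimate) else float(e))
            for m, e in metrics.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rank_predictors(
    estimates: Mapping[str, Mapping[str, object]],
    two_stage: bool = False,
    teams: Mapping[str, str] | None = None,
) -> RankingResult:
    """Rank predictors per metric (1 = best, average ranks on ties), then
    order by the mean of the three ranks.

    With ``two_stage``, predictors are first ranked within each team to
    pick a representative, and the representatives are re-ranked; baselines
    should be ranked in a separate call (separate pool).
    """
    table = _points(estimates)
    if two_stage:
        if teams is None:
            raise ValueError("two_stage ranking requires a team map")
        team_best: dict[str, str] = {}
        for team in sorted(set(teams.values())):
            members = [p for p in table.index if teams.get(p) == team]
            inner = rank_predictors({p: estimates[p] for p in members})
            team_best[team] = inner.order[0]
        result = rank_predictors({p: estimates[p] for p in team_best.values()})
        return RankingResult(
            result.per_metric_ranks, result.avg_rank, result.order, team_best
        )
    ranks = table.rank(ascending=False, method="average")
    avg = ranks.mean(axis=1)
    order = tuple(avg.sort_values(kind="stable").index)
    return RankingResult(ranks, avg, order)


def compare_binomial(
    draws_a: np.ndarray, draws_b: np.ndarray
) -> tuple[int, float]:
    """One-sided paired comparison: strict wins of a over b per bootstrap
    sample, with the exact upper-tail Binomial(n, 1/2) p-value P(X >= wins).

    Draws must come from shared bootstrap index sets (same seed and
    samples). The tail is computed in log space so extreme p-values stay
    representable.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"unpaired draw lengths: {a.shape} vs {b.shape}")
    n = len(a)
    wins = int(np.sum(a > b))
    if wins == 0:
        return 0, 1.0
    ks = np.arange(wins, n + 1)
    log_tail = stats.binom.logpmf(ks, n, 0.5)
    p = float(np.exp(np.logaddexp.reduce(log_tail)))
    return wins, min(p, 1.0)


def head_to_head(
    results: Mapping[str, Mapping[str, MetricEstimate]], metric: str
) -> pd.DataFrame:
    """Matrix of one-sided p-values: entry (a, b) tests a better than b."""
    names = list(results)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            _, p = compare_binomial(
                results[a][metric].draws, results[b][metric].draws
            )
            mat.loc[a, b] = p
    return mat


def pairwise_correlation_matrix(
    views: Mapping[str, Mapping[str, float]],
    truth: Mapping[str, float],
    variants: Sequence[str],
    metric: str = METRIC_PEARSON,
) -> pd.DataFrame:
    """Predictor-vs-predictor correlations with truth on the diagonal.

    All inputs must be on the regression (activity) view. Off-diagonal
    (i, j) correlates predictor i with predictor j; diagonal (i, i)
    correlates predictor i with the experimental activity.
    """
    if metric not in (METRIC_PEARSON, METRIC_KENDALL):
        raise ValueError("correlation matrix supports pearson or kendall_tau")
    fn = _METRIC_FNS[metric]
    names = list(views)
    cols = {n: np.array([views[n][v] for v in variants]) for n in names}
    t = np.array([truth[v] for v in variants])
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        mat.loc[a, a] = fn(t, cols[a])
        for b in names[i + 1 :]:
            r = fn(cols[a], cols[b])
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat
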