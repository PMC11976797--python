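"""Replicate-resampling upper bound on predictor performance.

The stochastic predictor answers a query for a variant by uniformly picking
one biological replicate containing it and then one technical-replicate
R-WT value within that replicate (two-level uniform, not pooled over all
technical values). Averaging the performance of many such realizations
quantifies assay self-consistency and bounds what any predictor of the
assay output can achieve.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from vepbench._rng import substream
from vepbench.assay import CONTROL_TAGS
from vepbench.metrics import (
    METRIC_AUC,
    METRIC_KENDALL,
    METRIC_PEARSON,
    METRICS,
    UndefinedMetricError,
    auc,
    kendall_tau,
    pearson,
)

#: variant -> list of biological replicates -> technical-replicate R-WT values
ReplicateIndex = dict[str, list[list[float]]]

_MAX_REDRAWS = 100


def build_replicate_index(normalized: pd.DataFrame) -> ReplicateIndex:
    """Group a normalized replicate table (``rwt`` column) by variant and
    biological replicate; control rows are dropped."""
    variants = normalized[~normalized["subject"].isin(CONTROL_TAGS)]
    index: ReplicateIndex = {}
    for (variant, _), grp in variants.groupby(["subject", "bio_rep"], sort=False):
        index.setdefault(variant, []).append([float(v) for v in grp["rwt"]])
    bad = [v for v, reps in index.items() if not reps or any(not r for r in reps)]
    if bad:
        raise ValueError(f"variants with empty replicate lists: {bad}")
    return index


def sample_prediction(
    variant: str, index: ReplicateIndex, rng: np.random.Generator
) -> float:
    """One stochastic prediction: uniform biological replicate, then uniform
    technical value within it. Biological replicates are equally likely
    regardless of how many technical values they hold."""
    try:
        bio_reps = index[variant]
    except KeyError:
        raise KeyError(f"variant {variant!r} not in replicate index") from None
    rep = bio_reps[rng.integers(len(bio_reps))]
    return rep[rng.integers(len(rep))]


def sample_realization(
    index: ReplicateIndex, variants: Sequence[str], rng: np.random.Generator
) -> dict[str, float]:
    """One full realization: a sampled prediction for every variant."""
    return {v: sample_prediction(v, index, rng) for v in variants}


def evaluate_experimental_max(
    index: ReplicateIndex,
    truth: Mapping[str, float],
    labels: Mapping[str, str],
    eval_variants: Sequence[str],
    n_realizations: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, object]]:
    """Mean performance and 90% percentile band over stochastic realizations.

    Each realization draws one prediction per evaluation-set variant and is
    scored against the all-replicate mean activity (Pearson, tau) and the
    binary labels (AUC, risk = negated sampled activity). Returns, per
    metric, the mean, the (5th, 95th) percentile interval and the raw
    per-realization values. Degenerate realizations are redrawn.
    """
    order = list(eval_variants)
    missing = [v for v in order if v not in index]
    if missing:
        raise KeyError(f"evaluation-set variants missing from index: {missing}")
    t = np.array([truth[v] for v in order])
    lab = np.array([labels[v] for v in order])
    rng = substream(seed, "experimental-max")
    draws = {m: np.empty(n_realizations) for m in METRICS}
    for i in range(n_realizations):
        for attempt in range(_MAX_REDRAWS + 1):
            pred = np.array([sample_prediction(v, index, rng) for v in order])
            try:
                draws[METRIC_PEARSON][i] = pearson(t, pred)
                draws[METRIC_KENDALL][i] = kendall_tau(t, pred)
                draws[METRIC_AUC][i] = auc(lab, -pred)
                break
            except UndefinedMetricError:
                if attempt == _MAX_REDRAWS:
                    raise
    out = {}
    for m in METRICS:
        lo, hi = np.percentile(draws[m], [5, 95])
        out[m] = {
            "mean": float(draws[m].mean()),
            "ci90": (float(lo), float(hi)),
            "draws": draws[m],
        }
    return out
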