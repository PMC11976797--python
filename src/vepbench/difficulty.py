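"""Per-variant prediction difficulty across competitive predictors.

A LoF variant's difficulty under a predictor is the false positive rate
obtained when the predictor's value at that variant is used as the
classification threshold: the fraction of WT-like variants predicted to
have strictly lower activity. Symmetrically, a WT-like variant's
difficulty is the false negative rate: the fraction of LoF variants
predicted strictly higher. Both rates use the activity-scale (regression)
view and are invariant under strictly increasing transforms of a
predictor's scores. Ties do not count toward either rate.

The analysis deliberately covers all assayed variants, including those
excluded from predictor comparison.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

from vepbench.assay import LOF, WT_LIKE
from vepbench.predictions import ROLE_PARTICIPANT


def variant_fpr(
    lof_variant: str,
    scores: Mapping[str, float],
    wt_like_set: Sequence[str],
) -> float:
    """Fraction of the WT-like set predicted strictly below the LoF variant."""
    if not wt_like_set:
        raise ValueError("empty WT-like set")
    probe = scores[lof_variant]
    below = sum(1 for w in wt_like_set if scores[w] < probe)
    return below / len(wt_like_set)


def variant_fnr(
    wt_variant: str,
    scores: Mapping[str, float],
    lof_set: Sequence[str],
) -> float:
    """Fraction of the LoF set predicted strictly above the WT-like variant."""
    if not lof_set:
        raise ValueError("empty LoF set")
    probe = scores[wt_variant]
    above = sum(1 for l in lof_set if scores[l] > probe)
    return above / len(lof_set)


def select_competitive(
    aucs: Mapping[str, float],
    auc_floor: float = 0.8,
    best_per_team: bool = True,
    roles: Mapping[str, str] | None = None,
    teams: Mapping[str, str] | None = None,
) -> list[str]:
    """Predictors entering the difficulty analysis.

    Participants are reduced to the best predictor per team (by AUC, or
    pass pre-selected representatives) and then filtered at AUC > floor;
    baselines are filtered at the floor only. Without role information all
    predictors are treated as one pool filtered at the floor.
    """
    roles = roles or {}
    selected: list[str] = []
    participants = [p for p in aucs if roles.get(p) == ROLE_PARTICIPANT]
    baselines = [p for p in aucs if roles.get(p) != ROLE_PARTICIPANT]
    if best_per_team and teams and participants:
        reps = []
        for team in sorted({teams[p] for p in participants if p in teams}):
            members = [p for p in participants if teams.get(p) == team]
            reps.append(max(members, key=lambda p: aucs[p]))
        participants = reps
    selected = [p for p in participants if aucs[p] > auc_floor]
    selected += [p for p in baselines if aucs[p] > auc_floor]
    if not selected:
        warnings.warn("no predictor passed the AUC floor; empty profile", stacklevel=2)
    return selected


def difficulty_profile(
    views: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, str],
    imputed: Mapping[str, frozenset[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPR and FNR matrices (variant rows, predictor columns) over all
    labeled variants, plus a cross-predictor ``average`` column.

    ``views`` maps predictor name to activity-scale scores covering every
    labeled variant (imputed entries participate; pass ``imputed`` to note
    them in the output attrs).
    """
    lof_set = [v for v, lab in labels.items() if lab == LOF]
    wt_set = [v for v, lab in labels.items() if lab == WT_LIKE]
    names = list(views)
    fpr = pd.DataFrame(
        {n: [variant_fpr(v, views[n], wt_set) for v in lof_set] for n in names},
        index=lof_set,
    )
    fnr = pd.DataFrame(
        {n: [variant_fnr(v, views[n], lof_set) for v in wt_set] for n in names},
        index=wt_set,
    )
    fpr["average"] = fpr[names].mean(axis=1)
    fnr["average"] = fnr[names].mean(axis=1)
    if imputed:
        note = {n: sorted(imputed.get(n, ())) for n in names}
        fpr.attrs["imputed"] = note
        fnr.attrs["imputed"] = note
    return fpr, fnr
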