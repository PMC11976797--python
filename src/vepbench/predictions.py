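"""Predictor score ingestion, orientation transforms, mean imputation.

Predictors come in two orientations: ``activity`` predictors estimate R-WT
activity directly (higher = more functional), while ``pathogenicity``
predictors emit a damage score in [0, 1] (higher = more damaging). Both are
mapped onto a common regression view (activity scale: pathogenicity scores
become 1 - score) and a common classification view (risk scale, higher =
more likely LoF: activity scores are negated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

ORIENT_ACTIVITY = "activity"
ORIENT_PATHOGENICITY = "pathogenicity"
ROLE_PARTICIPANT = "participant"
ROLE_BASELINE = "baseline"


class UnevaluablePredictorError(ValueError):
    """No non-missing score on the evaluation set; imputation impossible."""


@dataclass(frozen=True)
class PredictionSet:
    """One predictor's scores with declared orientation and provenance."""

    predictor: str
    orientation: str
    scores: Mapping[str, float]
    role: str = ROLE_BASELINE
    team: str | None = None
    imputed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.orientation not in (ORIENT_ACTIVITY, ORIENT_PATHOGENICITY):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.role not in (ROLE_PARTICIPANT, ROLE_BASELINE):
            raise ValueError(f"unknown role {self.role!r}")
        if not self.scores:
            raise ValueError(f"{self.predictor}: empty score set")
        if self.orientation == ORIENT_PATHOGENICITY:
            stray = [v for v, s in self.scores.items() if not 0.0 <= s <= 1.0]
            if stray:
                warnings.warn(
                    f"{self.predictor}: pathogenicity scores outside [0,1] "
                    f"for {stray[:5]}; transform still applies",
                    stacklevel=3,
                )

    def subset(self, variants: Sequence[str]) -> dict[str, float]:
        """Native-scale scores restricted to ``variants`` (missing dropped)."""
        return {v: self.scores[v] for v in variants if v in self.scores}


def regression_view(p: PredictionSet) -> dict[str, float]:
    """Scores on the activity scale (pathogenicity scores become 1 - score)."""
    if p.orientation == ORIENT_ACTIVITY:
        return dict(p.scores)
    return {v: 1.0 - s for v, s in p.scores.items()}


def classification_view(p: PredictionSet) -> dict[str, float]:
    """Scores as LoF risk, higher = more likely LoF (activity is negated)."""
    if p.orientation == ORIENT_ACTIVITY:
        return {v: -s for v, s in p.scores.items()}
    return dict(p.scores)


def impute_missing(p: PredictionSet, eval_variants: Sequence[str]) -> PredictionSet:
    """Fill missing scores on the evaluation set with the predictor's mean.

    The mean is taken over the predictor's non-missing native-scale scores
    within the evaluation set, before any orientation transform. Imputed
    variants are flagged in the returned set; present scores are unchanged.
    """
    present = p.subset(eval_variants)
    if not present:
        raise UnevaluablePredictorError(
            f"{p.predictor}: no scores on the evaluation set"
        )
    missing = [v for v in eval_variants if v not in p.scores]
    if not missing:
        return p
    fill = sum(present.values()) / len(present)
    scores = dict(p.scores)
    scores.update({v: fill for v in missing})
    return replace(p, scores=scores, imputed=p.imputed | frozenset(missing))


def load_scores(path) -> dict[str, float]:
    """Two-column (variant, score) TSV/CSV; empty or NA score = missing."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    df.columns = ["variant", "score", *df.columns[2:]]
    df = df.dropna(subset=["score"])
    return dict(zip(df["variant"], df["score"].astype(float)))


def load_manifest(path) -> list[PredictionSet]:
    """Load the predictor manifest (YAML list of name/orientation/role/
    team/scores entries; score paths are resolved relative to the manifest).
    """
    path = Path(path)
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        entries = entries.get("predictors", [])
    sets = []
    for entry in entries:
        scores = load_scores(path.parent / entry["scores"])
        sets.append(
            PredictionSet(
                predictor=entry["name"],
                orientation=entry["orientation"],
                scores=scores,
                role=entry.get("role", ROLE_BASELINE),
                team=entry.get("team"),
            )
        )
    return sets
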