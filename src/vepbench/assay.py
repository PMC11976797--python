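"""Assay data model: R-WT normalization, aggregation, labels, evaluation set.

Raw reporter readings arrive in long format keyed by
(subject, biological replicate, technical replicate), where ``subject`` is
either a protein-HGVS variant identifier or one of the reserved control tags
``WT`` (wildtype, positive control), ``EV`` (empty vector, baseline) and
``KD`` (kinase-dead control, carried but unused by computation). Every
(bio_rep, tech_rep) pair must contain a WT and an EV reading; activity is
normalized within that pair so that EV maps to 0 and WT maps to 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTROL_WT = "WT"
CONTROL_EV = "EV"
CONTROL_KD = "KD"
CONTROL_TAGS = frozenset({CONTROL_WT, CONTROL_EV, CONTROL_KD})

LOF = "LoF"
WT_LIKE = "WT-like"

#: mean R-WT activity below this value labels a variant loss-of-function
DEFAULT_LOF_THRESHOLD = 0.6

REPLICATE_COLUMNS = ("subject", "bio_rep", "tech_rep", "raw_activity")

_MISSENSE_RE = re.compile(r"^(?:p\.)?[A-Z]\d+[A-Z]$")


class DegenerateReplicateError(ValueError):
    """WT and EV readings coincide, so normalization is undefined."""


class ReplicateTableError(ValueError):
    """A replicate table violates the schema or control-coverage contract."""


class MissingVariantError(KeyError):
    """A variant has no replicate measurements."""


@dataclass(frozen=True)
class ReplicateMeasurement:
    """One raw activity reading from a single (bio, tech) replication."""

    subject: str
    bio_rep: str
    tech_rep: str
    raw_activity: float


@dataclass(frozen=True)
class GroundTruthEntry:
    """Per-variant aggregate of normalized replicate activity."""

    variant: str
    mean_rwt: float
    p25: float
    p75: float
    label: str

    def __post_init__(self) -> None:
        if self.p25 > self.p75:
            raise ValueError(f"{self.variant}: p25 {self.p25} > p75 {self.p75}")
        if self.label not in (LOF, WT_LIKE):
            raise ValueError(f"{self.variant}: bad label {self.label!r}")


@dataclass(frozen=True)
class VariantRecord:
    """Annotation for one variant: clinical status, population data, scores."""

    variant: str
    genomic: str | None = None
    clinvar_status: str | None = None  # P, LP, P/LP, VUS, VUS/LB, B/LB, LB, B
    hgmd_status: str | None = None  # DM, DM?
    gnomad_ac: int | None = None
    gnomad_af: float | None = None
    revel: float | None = None
    #: (variant, classification in {P, LP}, revel score) for same-residue variants
    colocated: tuple[tuple[str, str, float], ...] = ()
    gelshift_label: str | None = None

    def __post_init__(self) -> None:
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"{self.variant}: gnomad_af {self.gnomad_af} outside [0,1]")
        if self.gnomad_ac is not None and self.gnomad_ac < 0:
            raise ValueError(f"{self.variant}: negative gnomad_ac")

    @property
    def is_missense(self) -> bool:
        return bool(_MISSENSE_RE.match(self.variant))


@dataclass(frozen=True)
class EvaluationSet:
    """Retained variants plus the exclusions with reasons."""

    variants: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        dropped = {v for v, _ in self.excluded}
        overlap = dropped & set(self.variants)
        if overlap:
            raise ValueError(f"variants both retained and excluded: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant: str) -> bool:
        return variant in self.variants


def normalize_activity(
    raw_var: float,
    raw_ev: float,
    raw_wt: float,
    *,
    bio_rep: str | None = None,
    tech_rep: str | None = None,
) -> float:
    """Relative-wildtype activity: (var - EV) / (WT - EV).

    All three readings must come from the same (bio_rep, tech_rep) pair.
    EV maps to 0 and WT to 1 by construction.
    """
    denom = raw_wt - raw_ev
    if denom == 0:
        where = ""
        if bio_rep is not None or tech_rep is not None:
            where = f" in replicate (bio={bio_rep}, tech={tech_rep})"
        raise DegenerateReplicateError(f"WT and EV activity coincide ({raw_wt}){where}")
    return (raw_var - raw_ev) / denom


def load_replicate_table(path) -> pd.DataFrame:
    """Read a long-format replicate table (TSV or CSV) and validate it."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject": str, "bio_rep": str, "tech_rep": str})
    return validate_replicate_table(df)


def validate_replicate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the replicate-table contract, reporting every violation.

    Checks: required columns, unique (subject, bio_rep, tech_rep) keys,
    and a WT plus an EV reading in every (bio_rep, tech_rep) pair.
    """
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise ReplicateTableError(f"missing columns: {missing}")
    problems: list[str] = []
    key = ["subject", "bio_rep", "tech_rep"]
    dup = df[df.duplicated(key, keep=False)]
    if not dup.empty:
        keys = sorted(set(map(tuple, dup[key].itertuples(index=False))))
        problems.append(f"duplicate keys: {keys[:10]}")
    for (bio, tech), grp in df.groupby(["bio_rep", "tech_rep"], sort=False):
        subjects = set(grp["subject"])
        for tag in (CONTROL_WT, CONTROL_EV):
            if tag not in subjects:
                problems.append(f"replicate (bio={bio}, tech={tech}) lacks {tag} reading")
    if problems:
        raise ReplicateTableError("invalid replicate table:\n  " + "\n  ".join(problems))
    return df


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize every reading within its (bio_rep, tech_rep) pair.

    Returns the input columns plus an ``rwt`` column; control rows are
    retained (WT rows normalize to exactly 1, EV rows to exactly 0).
    """
    validate_replicate_table(df)
    out = []
    for (bio, tech), grp in df.groupby(["bio_rep", "tech_rep"], sort=False):
        wt = float(grp.loc[grp["subject"] == CONTROL_WT, "raw_activity"].iloc[0])
        ev = float(grp.loc[grp["subject"] == CONTROL_EV, "raw_activity"].iloc[0])
        rwt = grp["raw_activity"].map(
            lambda v: normalize_activity(v, ev, wt, bio_rep=bio, tech_rep=tech)
        )
        out.append(grp.assign(rwt=rwt))
    return pd.concat(out, ignore_index=True)


def classify_activity(mean_rwt: float, threshold: float = DEFAULT_LOF_THRESHOLD) -> str:
    """LoF iff mean R-WT activity is strictly below the threshold."""
    if not np.isfinite(mean_rwt):
        raise ValueError(f"non-finite mean R-WT activity: {mean_rwt}")
    return LOF if mean_rwt < threshold else WT_LIKE


def aggregate_replicates(
    rwt_values: Sequence[float] | Iterable[float],
    *,
    percentile_method: str = "linear",
) -> tuple[float, float, float]:
    """Mean and [25th, 75th] percentiles over per-replicate R-WT values.

    The percentile convention defaults to linear interpolation between order
    statistics; any numpy ``method`` name is accepted.
    """
    values = np.asarray(list(rwt_values), dtype=float)
    if values.size == 0:
        raise MissingVariantError("no replicate values to aggregate")
    mean = float(values.mean())
    p25, p75 = np.percentile(values, [25, 75], method=percentile_method)
    return mean, float(p25), float(p75)


def build_ground_truth(
    normalized: pd.DataFrame,
    *,
    threshold: float = DEFAULT_LOF_THRESHOLD,
    percentile_method: str = "linear",
) -> pd.DataFrame:
    """Aggregate a normalized replicate table into a per-variant truth table.

    Control rows are dropped. Returns columns
    (variant, mean_rwt, p25, p75, label), one row per variant, ordered by
    increasing mean activity.
    """
    variants = normalized[~normalized["subject"].isin(CONTROL_TAGS)]
    if variants.empty:
        raise MissingVariantError("replicate table contains no variant rows")
    rows = []
    for variant, grp in variants.groupby("subject", sort=False):
        mean, p25, p75 = aggregate_replicates(
            grp["rwt"], percentile_method=percentile_method
        )
        rows.append(
            {
                "variant": variant,
                "mean_rwt": mean,
                "p25": p25,
                "p75": p75,
                "label": classify_activity(mean, threshold),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("mean_rwt", kind="stable").reset_index(drop=True)
    )


def ground_truth_entries(table: pd.DataFrame) -> list[GroundTruthEntry]:
    return [
        GroundTruthEntry(r.variant, r.mean_rwt, r.p25, r.p75, r.label)
        for r in table.itertuples(index=False)
    ]


_CLINVAR_PATHOGENIC = frozenset({"P", "LP", "P/LP"})
_CLINVAR_BENIGN = frozenset({"B", "LB", "B/LB"})
_CLINVAR_UNCERTAIN = frozenset({"VUS", "VUS/LB"})


def has_definitive_assertion(record: VariantRecord) -> str | None:
    """Reason string if the record carries a non-conflicting definitive
    clinical assertion (ClinVar P/LP/B/LB or HGMD DM), else None.

    ``DM?`` never counts as a pathogenic assertion, and any uncertain or
    mixed ClinVar status (VUS, VUS/LB) marks the evidence as conflicting,
    so such variants are retained for evaluation.
    """
    clinvar = record.clinvar_status
    pathogenic = (clinvar in _CLINVAR_PATHOGENIC) or (record.hgmd_status == "DM")
    benign = clinvar in _CLINVAR_BENIGN
    uncertain = clinvar in _CLINVAR_UNCERTAIN
    if pathogenic and not benign and not uncertain:
        return f"definitive pathogenic assertion (ClinVar={clinvar}, HGMD={record.hgmd_status})"
    if benign and not pathogenic:
        return f"definitive benign assertion (ClinVar={clinvar})"
    return None


def build_evaluation_set(
    records: Sequence[VariantRecord], drop_non_missense: bool = False
) -> EvaluationSet:
    """Exclude definitively classified variants (and optionally non-missense).

    Variants with a non-conflicting P/LP/DM or B/LB assertion may have been
    used to train predictors and are removed; VUS, DM?, conflicting and
    unannotated variants are retained.
    """
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for record in records:
        reason = has_definitive_assertion(record)
        if reason is None and drop_non_missense and not record.is_missense:
            reason = "non-missense variant"
        if reason is None:
            kept.append(record.variant)
        else:
            excluded.append((record.variant, reason))
    return EvaluationSet(tuple(kept), tuple(excluded))
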