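"""ACMG/AMP point-based clinical variant classification.

Four evidence channels are combined on the signed point scale where
supporting / moderate / strong / very strong evidence is worth
1 / 2 / 4 / 8 points toward pathogenicity (negative toward benignity):

* functional (PS3/BS3): each assay contributes +1 for a LoF result and -1
  for a WT-like result, so concordant assays net +/-2 and discordant 0;
* population (PM2/BS1): absence from the population database gives PM2 +1;
  allele frequency above the BS1 threshold gives BS1 -4; presence below
  the threshold is indeterminate (no code);
* computational (PP3/BP4): graded by calibrated score intervals of a
  pathogenicity meta-score in [0, 1];
* co-located pathogenic variants (PM5): established P/LP missense changes
  at the same residue, gated by a 2-decimal score comparison.

Totals map to categories: P >= 10, LP [6, 9], VUS [0, 5] (split into
VUS-low [0, 1], VUS-mid [2, 3], VUS-high [4, 5]), LB [-6, -1], B <= -7.
Case-level codes (PM6/PS2, PP1) are accepted as manual pass-through items
but never derived automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from vepbench.assay import LOF, WT_LIKE, VariantRecord

POINTS_SUPPORTING = 1
POINTS_MODERATE = 2
POINTS_STRONG = 4
POINTS_VERY_STRONG = 8
_VALID_POINTS = frozenset({-8, -4, -2, -1, 1, 2, 4, 8})

_PATHOGENIC_CODES = frozenset({"PS3", "PP3", "PM2", "PM5", "PM6", "PS2", "PP1"})
_BENIGN_CODES = frozenset({"BS3", "BP4", "BS1"})

DEFAULT_BS1_AF = 0.001

#: [low, high) score intervals for PP3, strongest first
PP3_INTERVALS = (
    (0.932, 1.0, POINTS_STRONG),
    (0.773, 0.932, POINTS_MODERATE),
    (0.644, 0.773, POINTS_SUPPORTING),
)
#: (low, high] score intervals for BP4, weakest first
BP4_INTERVALS = (
    (0.183, 0.290, -POINTS_SUPPORTING),
    (0.016, 0.183, -POINTS_MODERATE),
    (0.003, 0.016, -POINTS_STRONG),
)

CATEGORY_P = "P"
CATEGORY_LP = "LP"
CATEGORY_VUS_HIGH = "VUS-high"
CATEGORY_VUS_MID = "VUS-mid"
CATEGORY_VUS_LOW = "VUS-low"
CATEGORY_LB = "LB"
CATEGORY_B = "B"

#: benign-to-pathogenic ordering of final categories
CATEGORY_ORDER = (
    CATEGORY_B,
    CATEGORY_LB,
    CATEGORY_VUS_LOW,
    CATEGORY_VUS_MID,
    CATEGORY_VUS_HIGH,
    CATEGORY_LP,
    CATEGORY_P,
)


@dataclass(frozen=True)
class EvidenceItem:
    code: str
    points: int
    rationale: str = ""

    def __post_init__(self) -> None:
        # PM5 accumulates over co-located variants, so any total in 1..8 is
        # admissible for it; every other code sits on the strength ladder.
        if self.code == "PM5":
            if not 1 <= self.points <= 8:
                raise ValueError(f"PM5: invalid accumulated points {self.points}")
        elif self.points not in _VALID_POINTS:
            raise ValueError(f"{self.code}: invalid point value {self.points}")
        if self.code in _PATHOGENIC_CODES and self.points < 0:
            raise ValueError(f"{self.code}: pathogenic code with negative points")
        if self.code in _BENIGN_CODES and self.points > 0:
            raise ValueError(f"{self.code}: benign code with positive points")


@dataclass(frozen=True)
class EvidenceProfile:
    variant: str
    items: tuple[EvidenceItem, ...]
    total: int = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", sum(i.points for i in self.items))
        object.__setattr__(self, "category", categorize(self.total))

    def points_for(self, *codes: str) -> int:
        return sum(i.points for i in self.items if i.code in codes)


def _round2(x: float) -> Decimal:
    # half-up rounding, independent of binary float representation
    return Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def functional_evidence(
    luciferase_label: str | None, gelshift_label: str | None
) -> list[EvidenceItem]:
    """PS3 +1 per assay calling LoF, BS3 -1 per assay calling WT-like.

    Concordant assays net +2 or -2; discordant assays cancel to 0. A
    missing label contributes nothing.
    """
    items = []
    for assay, label in (("luciferase", luciferase_label), ("gel-shift", gelshift_label)):
        if label is None:
            continue
        if label == LOF:
            items.append(EvidenceItem("PS3", POINTS_SUPPORTING, f"{assay} assay: LoF"))
        elif label == WT_LIKE:
            items.append(EvidenceItem("BS3", -POINTS_SUPPORTING, f"{assay} assay: WT-like"))
        else:
            raise ValueError(f"bad assay label {label!r}")
    return items


def population_evidence(
    gnomad_ac: int | None,
    gnomad_af: float | None,
    bs1_threshold: float = DEFAULT_BS1_AF,
) -> EvidenceItem | None:
    """PM2 +1 when absent from the population database; BS1 -4 above the
    frequency threshold; otherwise indeterminate (no code)."""
    absent = gnomad_ac is None or gnomad_ac == 0
    if absent:
        return EvidenceItem("PM2", POINTS_SUPPORTING, "absent from gnomAD")
    if gnomad_af is None:
        raise ValueError("allele count present without a frequency")
    if gnomad_af > bs1_threshold:
        return EvidenceItem("BS1", -POINTS_STRONG, f"AF {gnomad_af:g} > {bs1_threshold:g}")
    return None


def computational_evidence(revel: float | None) -> EvidenceItem | None:
    """PP3/BP4 graded by the calibrated score intervals; scores in the
    (0.290, 0.644) gap, at or below 0.003, or absent give no code."""
    if revel is None:
        return None
    if not 0.0 <= revel <= 1.0:
        raise ValueError(f"score {revel} outside [0, 1]")
    for low, high, pts in PP3_INTERVALS:
        hit = (low <= revel <= high) if high == 1.0 else (low <= revel < high)
        if hit:
            return EvidenceItem("PP3", pts, f"score {revel} in [{low}, {high})")
    for low, high, pts in BP4_INTERVALS:
        if low < revel <= high:
            return EvidenceItem("BP4", pts, f"score {revel} in ({low}, {high}]")
    return None


def colocated_evidence(
    revel: float | None,
    colocated: Sequence[tuple[str, str, float]],
) -> EvidenceItem | None:
    """PM5 from established P/LP changes at the same residue.

    The code triggers when the tested variant's score, rounded to 2
    decimals, is >= the (rounded) score of at least one co-located P/LP
    variant. When triggered, points accumulate over *all* co-located P/LP
    variants: +2 for the first P, +1 for the first LP, +1 for each
    additional P or LP. Co-located B/LB entries are ignored with a note.
    """
    usable = [(v, c, s) for v, c, s in colocated if c in ("P", "LP")]
    if revel is None or not usable:
        return None
    mine = _round2(revel)
    if not any(mine >= _round2(s) for _, _, s in usable):
        return None
    points = 0
    seen_p = False
    for _, cls, _ in usable:
        if cls == "P":
            points += POINTS_SUPPORTING if seen_p else POINTS_MODERATE
            seen_p = True
        else:
            points += POINTS_SUPPORTING
    detail = ", ".join(f"{v} ({c}, {s})" for v, c, s in usable)
    return EvidenceItem("PM5", min(points, 8), f"qualifying co-located: {detail}")


def categorize(total: int) -> str:
    """Map a point total to the final category (VUS split low/mid/high)."""
    if total >= 10:
        return CATEGORY_P
    if total >= 6:
        return CATEGORY_LP
    if total >= 4:
        return CATEGORY_VUS_HIGH
    if total >= 2:
        return CATEGORY_VUS_MID
    if total >= 0:
        return CATEGORY_VUS_LOW
    if total >= -6:
        return CATEGORY_LB
    return CATEGORY_B


def classify_variant_clinically(
    record: VariantRecord,
    luciferase_label: str | None,
    gelshift_label: str | None = None,
    bs1_threshold: float = DEFAULT_BS1_AF,
    manual_items: Sequence[EvidenceItem] = (),
) -> EvidenceProfile:
    """Assemble all four evidence channels for one variant.

    ``gelshift_label`` defaults to the record's own annotation. Extra
    ``manual_items`` (e.g., case-level codes) are appended verbatim.
    """
    if gelshift_label is None:
        gelshift_label = record.gelshift_label
    items = list(functional_evidence(luciferase_label, gelshift_label))
    pop = population_evidence(record.gnomad_ac, record.gnomad_af, bs1_threshold)
    if pop is not None:
        items.append(pop)
    comp = computational_evidence(record.revel)
    if comp is not None:
        items.append(comp)
    pm5 = colocated_evidence(record.revel, record.colocated)
    if pm5 is not None:
        items.append(pm5)
    items.extend(manual_items)
    return EvidenceProfile(record.variant, tuple(items))
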