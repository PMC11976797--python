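"""Packaged fixture tables: assayed-variant ground truth and the
classification-evidence table, transcribed once and checksummed.

``load_activity_fixture`` returns the per-variant mean R-WT activity with
dispersion percentiles, assay labels and clinical/population annotations;
``load_classification_fixture`` returns the per-variant classification
inputs (score, co-located variants, allele frequency) together with the
expected per-channel points, totals and categories used by golden tests.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import numpy as np
import pandas as pd

from vepbench.assay import GroundTruthEntry, VariantRecord

_DATA = resources.files("vepbench.data")


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


def _read(name: str) -> pd.DataFrame:
    path = _DATA / name
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = json.loads((_DATA / "checksums.json").read_text())[name]
    if digest != expected:
        raise FixtureIntegrityError(f"{name}: sha256 {digest} != recorded {expected}")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"variant": str})


def load_activity_fixture() -> pd.DataFrame:
    """28 assayed variants: annotations, mean R-WT, [p25, p75], labels."""
    return _read("activity_table.tsv")


def load_classification_fixture() -> pd.DataFrame:
    """28 variants with classification inputs and expected point breakdown."""
    df = _read("classification_table.tsv")
    df["prior_definitive"] = df["prior_definitive"].astype(bool)
    return df


def parse_colocated(cell: object) -> tuple[tuple[str, str, float], ...]:
    """Decode 'VAR|CLS|SCORE;...' cells into (variant, class, score) tuples."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    out = []
    for part in str(cell).split(";"):
        var, cls, score = part.split("|")
        out.append((var, cls, float(score)))
    return tuple(out)


def _opt(value, cast):
    return None if pd.isna(value) else cast(value)


def activity_records() -> list[VariantRecord]:
    """VariantRecords from the activity fixture (no computational scores)."""
    df = load_activity_fixture()
    return [
        VariantRecord(
            variant=r.variant,
            genomic=_opt(r.genomic, str),
            clinvar_status=_opt(r.clinvar, str),
            hgmd_status=_opt(r.hgmd, str),
            gnomad_ac=_opt(r.gnomad_ac, int),
            gnomad_af=_opt(r.gnomad_af, float),
            gelshift_label=r.gelshift_label,
        )
        for r in df.itertuples(index=False)
    ]


def classification_records() -> list[tuple[VariantRecord, str]]:
    """(VariantRecord, luciferase label) pairs with full classification
    inputs, merging population counts from the activity fixture."""
    activity = load_activity_fixture().set_index("variant")
    rows = []
    for r in load_classification_fixture().itertuples(index=False):
        act = activity.loc[r.variant]
        luciferase, gelshift = str(r.assay_result).split("-")
        record = VariantRecord(
            variant=r.variant,
            clinvar_status=_opt(r.clinvar, str),
            hgmd_status=_opt(r.hgmd, str),
            gnomad_ac=_opt(act["gnomad_ac"], int),
            gnomad_af=_opt(r.gnomad_af, float),
            revel=_opt(r.revel, float),
            colocated=parse_colocated(r.colocated),
            gelshift_label="WT-like" if gelshift == "WT" else gelshift,
        )
        rows.append((record, "WT-like" if luciferase == "WT" else luciferase))
    return rows


def ground_truth_entries() -> list[GroundTruthEntry]:
    df = load_activity_fixture()
    return [
        GroundTruthEntry(r.variant, r.mean_rwt, r.p25, r.p75, r.luciferase_label)
        for r in df.itertuples(index=False)
    ]
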