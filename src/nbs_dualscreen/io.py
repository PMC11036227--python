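"""TSV readers and writers for the package's tabular interfaces.

All tables are UTF-8 TSV with declared headers and decimal points. The
formats round-trip: writing then reading any table is the identity on
records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from nbs_dualscreen.errors import ValidationError
from nbs_dualscreen.msms_rules import AnalyteProfile, CutoffSet, MarkerCutoff
from nbs_dualscreen.screen_rules import (
    GeneSpec,
    GeneticScreenResult,
    GenotypeRecord,
    Inheritance,
    Sex,
    VariantCall,
)
from nbs_dualscreen.workflow import DiagnosisRecord, SubjectOutcome

VARIANT_COLUMNS = ["subject_id", "sex", "gene", "variant_id", "acmg_class", "zygosity"]
PANEL_COLUMNS = ["gene", "inheritance", "in_panel", "disease", "group"]
ANALYTE_COLUMNS = ["subject_id", "marker", "value", "unit"]
CUTOFF_COLUMNS = ["center_id", "marker", "threshold", "direction", "unit"]
OUTCOME_COLUMNS = [
    "subject_id", "center", "ngs_call", "msms_call", "recalled", "confirmed", "disease",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def read_variant_table(path: str | Path) -> list[GenotypeRecord]:
    """One row per variant call; subjects with no row are absent (callers
    needing the full cohort should merge with a subject roster)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, VARIANT_COLUMNS, "variant table")
    records = []
    for (subject, sex), group in df.groupby(["subject_id", "sex"], sort=False):
        variants = tuple(
            VariantCall(row.gene, row.variant_id, row.acmg_class, row.zygosity)
            for row in group.itertuples()
        )
        records.append(GenotypeRecord(subject, Sex(sex), variants))
    return records


def write_variant_table(records: Iterable[GenotypeRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "sex": r.sex.value,
            "gene": v.gene_symbol,
            "variant_id": v.variant_id,
            "acmg_class": v.acmg_class.value,
            "zygosity": v.zygosity.value,
        }
        for r in records
        for v in r.variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel_table(path: str | Path) -> dict[str, GeneSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PANEL_COLUMNS, "panel table")
    panel = {}
    for row in df.itertuples():
        panel[row.gene] = GeneSpec(
            gene_symbol=row.gene,
            inheritance=Inheritance(row.inheritance),
            in_panel=str(row.in_panel).strip().lower() in ("true", "1", "yes"),
            disease_name=row.disease if isinstance(row.disease, str) else "",
        )
    return panel


def write_panel_table(panel: Mapping[str, GeneSpec], path: str | Path) -> None:
    rows = [
        {
            "gene": g.gene_symbol,
            "inheritance": g.inheritance.value,
            "in_panel": str(g.in_panel).lower(),
            "disease": g.disease_name,
            "group": g.disease_group.value,
        }
        for g in panel.values()
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_analyte_table(path: str | Path) -> list[AnalyteProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "marker": str})
    _require_columns(df, ANALYTE_COLUMNS[:3], "analyte table")
    profiles = []
    for subject, group in df.groupby("subject_id", sort=False):
        values = {row.marker: float(row.value) for row in group.itertuples()}
        profiles.append(AnalyteProfile(subject, values))
    return profiles


def write_analyte_table(
    profiles: Iterable[AnalyteProfile], path: str | Path, unit: str = "umol/L"
) -> None:
    rows = [
        {"subject_id": p.subject_id, "marker": m, "value": v, "unit": unit}
        for p in profiles
        for m, v in sorted(p.values.items())
    ]
    pd.DataFrame(rows, columns=ANALYTE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cutoff_table(path: str | Path, center: str | None = None) -> CutoffSet:
    df = pd.read_csv(path, sep="\t", dtype={"center_id": str, "marker": str})
    _require_columns(df, CUTOFF_COLUMNS[:4], "cutoff table")
    if center is not None:
        df = df[df["center_id"] == center]
        if df.empty:
            raise ValidationError(f"no cutoffs for center {center!r}")
    centers = df["center_id"].unique()
    if len(centers) != 1:
        raise ValidationError(
            f"cutoff table spans centers {sorted(centers)}; pass center="
        )
    cutoffs = {}
    for row in df.itertuples():
        unit = row.unit if "unit" in df.columns and isinstance(row.unit, str) else "umol/L"
        cutoffs[row.marker] = MarkerCutoff(
            row.marker, float(row.threshold), row.direction, unit
        )
    return CutoffSet(str(centers[0]), cutoffs)


def write_cutoff_table(cutoffs: CutoffSet, path: str | Path) -> None:
    rows = [
        {
            "center_id": cutoffs.center_id,
            "marker": c.marker_name,
            "threshold": c.threshold,
            "direction": c.direction,
            "unit": c.unit,
        }
        for c in (cutoffs.cutoffs[m] for m in sorted(cutoffs.cutoffs))
    ]
    pd.DataFrame(rows, columns=CUTOFF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_outcome_table(path: str | Path) -> list[SubjectOutcome]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, OUTCOME_COLUMNS, "outcome table")
    outcomes = []
    for row in df.itertuples():
        confirmed = str(row.confirmed).strip().lower() in ("true", "1", "yes")
        disease = row.disease if isinstance(row.disease, str) and row.disease else None
        outcomes.append(
            SubjectOutcome(
                subject_id=row.subject_id,
                center_id=row.center,
                ngs_call=row.ngs_call,
                msms_call=row.msms_call,
                recalled=str(row.recalled).strip().lower() in ("true", "1", "yes"),
                diagnosis=DiagnosisRecord(row.subject_id, confirmed, disease),
            )
        )
    return outcomes


def write_outcome_table(outcomes: Iterable[SubjectOutcome], path: str | Path) -> None:
    rows = [
        {
            "subject_id": o.subject_id,
            "center": o.center_id,
            "ngs_call": o.ngs_call,
            "msms_call": o.msms_call,
            "recalled": str(o.recalled).lower(),
            "confirmed": str(o.diagnosis.confirmed).lower(),
            "disease": o.diagnosis.disease_name or "",
        }
        for o in outcomes
    ]
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(path, sep="\t", index=False)


def write_genetic_results(
    results: Iterable[GeneticScreenResult], path: str | Path
) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "call": r.call,
            "triggering_gene": r.triggering_gene or "",
            "qualifying_alleles": r.qualifying_alleles,
            "reason": r.reason,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
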