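"""Packaged study fixtures.

Three published summary tables from the multicenter screening study are
transcribed as TSV resources:

* ``table1`` — per-disease diagnosed case counts, observed incidence and
  carrier frequencies among the 29,601 screened newborns;
* ``table2`` — per-center screening counts for both modalities
  (positives, recalls, confirmed cases, false negatives);
* ``table3`` — the 23 diagnosed subjects: genotypes (gene, variant, ACMG
  class, zygosity), primary and recall analyte values with their
  center-specific cutoffs, both screen calls, and the confirmed disorder.

Loaders verify pinned SHA-256 checksums and basic schema invariants
(exactly 23 table-3 subjects; table-2 center totals summing to 29,601)
before returning typed records.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from nbs_dualscreen.errors import FixtureIntegrityError
from nbs_dualscreen.msms_rules import (
    AnalyteProfile,
    CutoffSet,
    MarkerCutoff,
    default_direction,
)
from nbs_dualscreen.screen_rules import (
    GeneSpec,
    GenotypeRecord,
    Inheritance,
    Sex,
    VariantCall,
)
from nbs_dualscreen.workflow import DiagnosisRecord, SubjectOutcome

N_SCREENED = 29601

FIXTURE_SHA256 = {
    "table1_incidence.tsv": "dfe5a78fced0640af6a677bf70136b8d9d7179d32a31fa7d58fe2cc9e34b4167",
    "table2_performance.tsv": "0d7fff033340c4ff1401ae6034d5c5c54e6e5d66cce9ee4ca44040eee3d4a4e4",
    "table3_subjects.tsv": "31a29b1a61a57f652e08cc5048110967b36c4584cf438ce16f8424ccb9f2110e",
    "table3_variants.tsv": "114d1b4d511e1f1d64017310f511d3c06788bf1ae17b187d63606a1daaf3db58",
    "table3_analytes.tsv": "70a133fc6c9dcc56a5e1edfb20ede25e0a15191d69b2354e5ed58b1dcaf44245",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("nbs_dualscreen").joinpath("data", name)
    raw = ref.read_bytes()
    expected = FIXTURE_SHA256.get(name)
    if expected is not None:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != expected:
            raise FixtureIntegrityError(
                f"{name}: checksum {digest} != pinned {expected}"
            )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str)


@dataclass(frozen=True)
class DiseaseRow:
    disease: str
    gene: str
    n_cases: int
    incidence_reciprocal: int
    carrier_reciprocal: Optional[int]
    in_panel: bool


@dataclass(frozen=True)
class CenterCounts:
    center: str
    n_screened: int
    msms_positive: int
    msms_recalled: int
    msms_confirmed: int
    msms_false_negative: int
    ngs_positive: int
    ngs_recalled: int
    ngs_confirmed: int
    ngs_false_negative: int


@dataclass(frozen=True)
class Table3Subject:
    subject_id: str
    genetic_call: str
    msms_call: str
    disorder: str
    genotype: GenotypeRecord
    primary_profile: AnalyteProfile
    primary_cutoffs: CutoffSet
    recall_profile: Optional[AnalyteProfile]
    recall_cutoffs: Optional[CutoffSet]


def load_table1() -> list[DiseaseRow]:
    df = _read("table1_incidence.tsv")
    rows = []
    for r in df.itertuples():
        carrier = r.carrier_reciprocal
        rows.append(
            DiseaseRow(
                disease=r.disease,
                gene=r.gene,
                n_cases=int(r.n_cases),
                incidence_reciprocal=int(r.incidence_reciprocal),
                carrier_reciprocal=int(carrier) if isinstance(carrier, str) else None,
                in_panel=str(r.in_panel).lower() == "true",
            )
        )
    if sum(r.n_cases for r in rows) != 23:
        raise FixtureIntegrityError("table1 case counts must sum to 23")
    return rows


def load_table2() -> list[CenterCounts]:
    df = _read("table2_performance.tsv")
    rows = [
        CenterCounts(
            center=r.center,
            n_screened=int(r.n_screened),
            msms_positive=int(r.msms_positive),
            msms_recalled=int(r.msms_recalled),
            msms_confirmed=int(r.msms_confirmed),
            msms_false_negative=int(r.msms_false_negative),
            ngs_positive=int(r.ngs_positive),
            ngs_recalled=int(r.ngs_recalled),
            ngs_confirmed=int(r.ngs_confirmed),
            ngs_false_negative=int(r.ngs_false_negative),
        )
        for r in df.itertuples()
    ]
    if sum(r.n_screened for r in rows) != N_SCREENED:
        raise FixtureIntegrityError(
            f"table2 center totals must sum to {N_SCREENED}"
        )
    return rows


def table3_panel() -> dict[str, GeneSpec]:
    """Gene panel for the diagnosed-subject fixtures (from table 1; every
    gene autosomal recessive, ETFA off-panel)."""
    return {
        row.gene: GeneSpec(
            gene_symbol=row.gene,
            inheritance=Inheritance.AR,
            in_panel=row.in_panel,
            disease_name=row.disease,
        )
        for row in load_table1()
    }


def _profiles_by_stage(
    df: pd.DataFrame, subject: str, stage: str
) -> tuple[Optional[AnalyteProfile], Optional[CutoffSet]]:
    sub = df[(df["subject_id"] == subject) & (df["stage"] == stage)]
    if sub.empty:
        return None, None
    values: dict[str, float] = {}
    cutoffs: dict[str, MarkerCutoff] = {}
    for r in sub.itertuples():
        values[r.marker] = float(r.value)
        if isinstance(r.cutoff, str) and r.cutoff.strip():
            cutoffs[r.marker] = MarkerCutoff(
                r.marker, float(r.cutoff), default_direction(r.marker), r.unit
            )
    profile = AnalyteProfile(subject, values)
    cutset = CutoffSet(center_id=f"{subject}-{stage}", cutoffs=cutoffs)
    return profile, cutset


def load_table3() -> list[Table3Subject]:
    subjects_df = _read("table3_subjects.tsv")
    variants_df = _read("table3_variants.tsv")
    analytes_df = _read("table3_analytes.tsv")

    if len(subjects_df) != 23:
        raise FixtureIntegrityError("table3 must contain exactly 23 subjects")

    out = []
    for s in subjects_df.itertuples():
        vsub = variants_df[variants_df["subject_id"] == s.subject_id]
        variants = tuple(
            VariantCall(r.gene, r.variant_id, r.acmg_class, r.zygosity)
            for r in vsub.itertuples()
        )
        genotype = GenotypeRecord(s.subject_id, Sex(s.sex), variants)
        primary, primary_cuts = _profiles_by_stage(analytes_df, s.subject_id, "primary")
        recall, recall_cuts = _profiles_by_stage(analytes_df, s.subject_id, "recall")
        if primary is None:
            raise FixtureIntegrityError(f"{s.subject_id}: no primary analytes")
        out.append(
            Table3Subject(
                subject_id=s.subject_id,
                genetic_call=s.genetic_call,
                msms_call=s.msms_call,
                disorder=s.disorder,
                genotype=genotype,
                primary_profile=primary,
                primary_cutoffs=primary_cuts,
                recall_profile=recall,
                recall_cutoffs=recall_cuts,
            )
        )
    return out


def load_fixtures(name: str):
    """Dispatch loader: name in {"table1", "table2", "table3"}."""
    loaders = {"table1": load_table1, "table2": load_table2, "table3": load_table3}
    try:
        return loaders[name]()
    except KeyError:
        raise FixtureIntegrityError(f"unknown fixture {name!r}") from None


def table3_outcomes() -> list[SubjectOutcome]:
    """The 23 diagnosed subjects as labelled-ready outcome records.

    All 23 were referred (at least one screen positive) and recalled, and
    all 23 were confirmed; center assignment is not printed per subject
    and is recorded as the pooled pseudo-center "all".
    """
    return [
        SubjectOutcome(
            subject_id=s.subject_id,
            center_id="all",
            ngs_call=s.genetic_call,
            msms_call=s.msms_call,
            recalled=True,
            diagnosis=DiagnosisRecord(s.subject_id, True, s.disorder),
        )
        for s in load_table3()
    ]
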