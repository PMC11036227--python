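"""Genotype-based screen positivity.

A gene-panel screening result is positive when a subject carries
pathogenic (P) or likely pathogenic (LP) variants in an in-panel gene in a
configuration that matches the gene's inheritance pattern, judged without
knowledge of phenotype:

* autosomal recessive (AR): homozygous P/LP, or two distinct heterozygous
  P/LP variants (assumed in trans — phase is unobserved in singleton
  newborn sequencing, so compound heterozygosity is presumed);
* X-linked (XL), male: any single P/LP allele (hemizygous, or reported het
  by a caller unaware of sex);
* X-linked, female: homozygous P/LP only, unless the gene is explicitly
  configured to report heterozygous females.

Variants of uncertain significance (VUS) and benign classes never
contribute, even alongside a P allele. Off-panel genes never trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from nbs_dualscreen.errors import ContractViolation, ValidationError


class Inheritance(str, Enum):
    AR = "AR"
    XL = "XL"


class AcmgClass(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


#: pathogenicity ordering, benign to pathogenic (used by monotonicity tests)
ACMG_ORDER = (AcmgClass.B, AcmgClass.LB, AcmgClass.VUS, AcmgClass.LP, AcmgClass.P)

QUALIFYING_CLASSES = frozenset({AcmgClass.P, AcmgClass.LP})


class Zygosity(str, Enum):
    het = "het"
    hom = "hom"
    hemi = "hemi"


class Sex(str, Enum):
    M = "M"
    F = "F"


class DiseaseGroup(str, Enum):
    AA = "AA"
    OA = "OA"
    FAOD = "FAOD"
    other = "other"


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene screening metadata.

    ``xl_het_female_positive`` widens the XL rule so heterozygous females
    screen positive for this gene; the default (False) matches the study
    convention, which reports no heterozygous-female positives.
    """

    gene_symbol: str
    inheritance: Inheritance
    in_panel: bool = True
    disease_name: str = ""
    disease_group: DiseaseGroup = DiseaseGroup.other
    xl_het_female_positive: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")


@dataclass(frozen=True)
class VariantCall:
    gene_symbol: str
    variant_id: str
    acmg_class: AcmgClass
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        # coerce plain strings for ergonomic construction
        object.__setattr__(self, "acmg_class", AcmgClass(self.acmg_class))
        object.__setattr__(self, "zygosity", Zygosity(self.zygosity))


@dataclass(frozen=True)
class GenotypeRecord:
    """One subject's variant calls across the panel; may be empty."""

    subject_id: str
    sex: Sex
    variants: tuple[VariantCall, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "variants", tuple(self.variants))
        seen: set[tuple[str, str]] = set()
        for v in self.variants:
            key = (v.gene_symbol, v.variant_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate variant {v.variant_id} in {v.gene_symbol} "
                    f"for subject {self.subject_id}"
                )
            seen.add(key)

    def variants_in_gene(self, gene_symbol: str) -> tuple[VariantCall, ...]:
        return tuple(v for v in self.variants if v.gene_symbol == gene_symbol)


@dataclass(frozen=True)
class GeneticScreenResult:
    subject_id: str
    call: str  # "positive" | "negative"
    triggering_gene: Optional[str] = None
    qualifying_alleles: int = 0
    reason: str = ""

    def __post_init__(self) -> None:
        if self.call not in ("positive", "negative"):
            raise ValidationError(f"invalid call {self.call!r}")
        if (self.call == "positive") != (self.triggering_gene is not None):
            raise ValidationError(
                "triggering_gene must be set exactly when call is positive"
            )

    @property
    def positive(self) -> bool:
        return self.call == "positive"


def qualifying_allele_count(variants_in_gene: Sequence[VariantCall]) -> int:
    """Count P/LP alleles in one gene: hom contributes 2, het/hemi 1.

    VUS, LB and B calls never contribute. All calls must share a single
    gene symbol.
    """
    genes = {v.gene_symbol for v in variants_in_gene}
    if len(genes) > 1:
        raise ContractViolation(f"mixed gene symbols: {sorted(genes)}")
    count = 0
    for v in variants_in_gene:
        if v.acmg_class not in QUALIFYING_CLASSES:
            continue
        count += 2 if v.zygosity is Zygosity.hom else 1
    return count


def _gene_triggers(
    spec: GeneSpec, variants: Sequence[VariantCall], sex: Sex
) -> tuple[bool, int]:
    """Apply the inheritance-pattern rule for one gene."""
    n_qual = qualifying_allele_count(variants)
    qual = [v for v in variants if v.acmg_class in QUALIFYING_CLASSES]
    if spec.inheritance is Inheritance.AR:
        # hom (contributes 2) or >=2 distinct het P/LP variants assumed in trans
        return n_qual >= 2, n_qual
    # X-linked
    if sex is Sex.M:
        return n_qual >= 1, n_qual
    if spec.xl_het_female_positive:
        return n_qual >= 1, n_qual
    return any(v.zygosity is Zygosity.hom for v in qual), n_qual


def classify_genetic(
    record: GenotypeRecord, panel: Mapping[str, GeneSpec]
) -> GeneticScreenResult:
    """Screen one subject's genotype against the panel.

    Positive iff some in-panel gene satisfies its inheritance rule. The
    first triggering gene in lexicographic order is reported as
    ``triggering_gene``; all triggering genes appear in ``reason``. A
    subject positive for several genes is still a single positive.
    """
    by_gene: dict[str, list[VariantCall]] = {}
    for v in record.variants:
        if v.zygosity is Zygosity.hemi:
            if record.sex is Sex.F:
                raise ValidationError(
                    f"hemizygous call {v.variant_id} in female subject "
                    f"{record.subject_id}"
                )
            spec = panel.get(v.gene_symbol)
            if spec is not None and spec.inheritance is not Inheritance.XL:
                raise ValidationError(
                    f"hemizygous call in non-XL gene {v.gene_symbol}"
                )
        by_gene.setdefault(v.gene_symbol, []).append(v)

    triggers: list[tuple[str, int]] = []
    off_panel: list[str] = []
    for gene in sorted(by_gene):
        spec = panel.get(gene)
        if spec is None or not spec.in_panel:
            off_panel.append(gene)
            continue
        hit, n_qual = _gene_triggers(spec, by_gene[gene], record.sex)
        if hit:
            triggers.append((gene, n_qual))

    if triggers:
        gene, n_qual = triggers[0]
        reason = "P/LP alleles matching inheritance pattern in " + ", ".join(
            g for g, _ in triggers
        )
        return GeneticScreenResult(
            subject_id=record.subject_id,
            call="positive",
            triggering_gene=gene,
            qualifying_alleles=n_qual,
            reason=reason,
        )
    parts = ["no gene met its inheritance-pattern rule"]
    if off_panel:
        parts.append("off-panel genes ignored: " + ", ".join(sorted(off_panel)))
    return GeneticScreenResult(
        subject_id=record.subject_id,
        call="negative",
        reason="; ".join(parts),
    )


@dataclass(frozen=True)
class CohortGeneticResult:
    """Order-preserving per-subject results plus the positive tally."""

    results: tuple[GeneticScreenResult, ...]

    @property
    def n_positive(self) -> int:
        return sum(r.positive for r in self.results)

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)


def classify_cohort_genetic(
    records: Iterable[GenotypeRecord], panel: Mapping[str, GeneSpec]
) -> CohortGeneticResult:
    """Classify a cohort; subject ids must be unique."""
    records = list(records)
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate subject ids: {dupes}")
    return CohortGeneticResult(
        results=tuple(classify_genetic(r, panel) for r in records)
    )
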