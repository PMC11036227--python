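"""Carrier frequencies, Hardy-Weinberg incidence projection, variant spectra.

Carriers are unaffected heterozygotes for at least one qualifying allele
of a gene. With carrier frequency c and pathogenic allele frequency q,
random mating gives c = 2q(1-q) and disease incidence q². Two inversion
modes are provided:

* ``rare`` (default): q ≈ c/2, incidence (c/2)² — the classical rare-
  disease approximation;
* ``exact``: q = (1 - sqrt(1 - 2c)) / 2, the exact root of 2q(1-q) = c
  with q ≤ 1/2 (real only for c ≤ 1/2).

For c ≤ 1/40 the two modes agree within a few percent relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

from nbs_dualscreen.errors import ValidationError
from nbs_dualscreen.screen_rules import (
    GeneSpec,
    GenotypeRecord,
    Inheritance,
    QUALIFYING_CLASSES,
    Sex,
    Zygosity,
    classify_genetic,
)

CountingRule = Literal["any_PLP_het_carrier", "any_variant_carrier"]
HwMode = Literal["rare", "exact"]


@dataclass(frozen=True)
class CarrierEstimate:
    gene_symbol: str
    n_carriers: int
    n_screened: int

    def __post_init__(self) -> None:
        if self.n_carriers > self.n_screened:
            raise ValidationError("carriers exceed screened")

    @property
    def carrier_frequency(self) -> float:
        return self.n_carriers / self.n_screened

    @property
    def one_in_n(self) -> Optional[int]:
        """The N of the conventional "1 in N" rendering."""
        if self.n_carriers == 0:
            return None
        return round(self.n_screened / self.n_carriers)

    def __str__(self) -> str:
        if self.one_in_n is None:
            return f"{self.gene_symbol}: no carriers observed"
        return f"{self.gene_symbol}: 1 in {self.one_in_n}"


@dataclass(frozen=True)
class HwProjection:
    gene_symbol: str
    carrier_frequency: float
    allele_frequency: float
    projected_incidence: float
    mode: HwMode

    @property
    def one_in_n(self) -> int:
        return round(1.0 / self.projected_incidence)


@dataclass(frozen=True)
class VariantTally:
    gene_symbol: str
    variant_id: str
    n_alleles: int
    center_breakdown: Mapping[str, int]

    def __post_init__(self) -> None:
        breakdown = dict(self.center_breakdown)
        if sum(breakdown.values()) != self.n_alleles:
            raise ValidationError(
                f"{self.variant_id}: center counts do not sum to n_alleles"
            )
        object.__setattr__(self, "center_breakdown", breakdown)


def _is_affected(record: GenotypeRecord, spec: GeneSpec) -> bool:
    """Screen-positive for this gene alone <=> genotype qualifies as affected."""
    gene_vars = record.variants_in_gene(spec.gene_symbol)
    if not gene_vars:
        return False
    sub = GenotypeRecord(record.subject_id, record.sex, gene_vars)
    return classify_genetic(sub, {spec.gene_symbol: spec}).positive


def carrier_frequency(
    genotypes: Sequence[GenotypeRecord],
    gene: str,
    panel: Mapping[str, GeneSpec],
    counting_rule: CountingRule = "any_PLP_het_carrier",
    include_affected: bool = False,
) -> CarrierEstimate:
    """Count unaffected subjects with >= 1 qualifying het allele in ``gene``.

    ``any_PLP_het_carrier`` counts only P/LP heterozygotes (the default;
    VUS carriers excluded); ``any_variant_carrier`` counts a heterozygote
    for any reported class. Biallelic (affected) subjects are excluded
    from the numerator unless ``include_affected`` is set.
    """
    if not genotypes:
        raise ValidationError("empty cohort")
    spec = panel.get(gene)
    if spec is None:
        raise ValidationError(f"gene {gene!r} absent from panel")
    if counting_rule not in ("any_PLP_het_carrier", "any_variant_carrier"):
        raise ValidationError(f"unknown counting rule {counting_rule!r}")

    n_carriers = 0
    for rec in genotypes:
        gene_vars = rec.variants_in_gene(gene)
        if not gene_vars:
            continue
        het = [v for v in gene_vars if v.zygosity is Zygosity.het]
        if counting_rule == "any_PLP_het_carrier":
            het = [v for v in het if v.acmg_class in QUALIFYING_CLASSES]
        if not het:
            continue
        if not include_affected and _is_affected(rec, spec):
            continue
        n_carriers += 1
    return CarrierEstimate(gene, n_carriers, len(genotypes))


def hw_project_incidence(
    c: float, mode: HwMode = "rare", gene_symbol: str = ""
) -> HwProjection:
    """Project disease incidence q² from carrier frequency c under HWE."""
    if not 0.0 < c < 1.0:
        raise ValidationError(f"carrier frequency {c} not in (0, 1)")
    if mode == "rare":
        q = c / 2.0
    elif mode == "exact":
        if c > 0.5:
            raise ValidationError(
                f"2q(1-q) = {c} has no real solution with q <= 1/2"
            )
        q = (1.0 - math.sqrt(1.0 - 2.0 * c)) / 2.0
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return HwProjection(
        gene_symbol=gene_symbol,
        carrier_frequency=c,
        allele_frequency=q,
        projected_incidence=q * q,
        mode=mode,
    )


def variant_spectrum(
    genotypes: Sequence[GenotypeRecord],
    centers: Mapping[str, str] | Sequence[str],
    gene: str,
    top_n: int = 10,
) -> list[VariantTally]:
    """Top-N allele tallies for one gene with per-center breakdown.

    ``centers`` maps subject_id → center_id (or is a parallel sequence).
    Homozygotes contribute 2 alleles, het/hemi 1. Sorted by descending
    allele count, ties broken lexicographically by variant id.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    if not isinstance(centers, Mapping):
        if len(centers) != len(genotypes):
            raise ValidationError("centers sequence length mismatch")
        centers = {r.subject_id: c for r, c in zip(genotypes, centers)}

    totals: dict[str, int] = {}
    breakdown: dict[str, dict[str, int]] = {}
    for rec in genotypes:
        center = centers.get(rec.subject_id, "unknown")
        for v in rec.variants_in_gene(gene):
            n = 2 if v.zygosity is Zygosity.hom else 1
            totals[v.variant_id] = totals.get(v.variant_id, 0) + n
            per = breakdown.setdefault(v.variant_id, {})
            per[center] = per.get(center, 0) + n

    order = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        VariantTally(gene, vid, n, breakdown[vid]) for vid, n in order[:top_n]
    ]
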