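"""Genotype-based screen positivity: allele counting, inheritance-pattern
matching, cohort classification, and equivalence with a brute-force rule
oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbs_dualscreen.errors import ContractViolation, ValidationError
from nbs_dualscreen.screen_rules import (
    ACMG_ORDER,
    AcmgClass,
    GeneSpec,
    GenotypeRecord,
    Inheritance,
    Sex,
    VariantCall,
    Zygosity,
    classify_cohort_genetic,
    classify_genetic,
    qualifying_allele_count,
)

AR_PANEL = {"G1": GeneSpec("G1", Inheritance.AR)}
XL_PANEL = {"GX": GeneSpec("GX", Inheritance.XL)}


def vc(gene, vid, klass, zyg):
    return VariantCall(gene, vid, klass, zyg)


class TestQualifyingAlleleCount:
    @pytest.mark.parametrize(
        "variants, expected",
        [
            # homozygous LP counts two alleles
            ([vc("MMAA", "c.365T>C", "LP", "hom")], 2),
            # LP het + VUS het: only the LP allele qualifies
            (
                [
                    vc("ACADS", "c.322G>A", "LP", "het"),
                    vc("ACADS", "c.779G>T", "VUS", "het"),
                ],
                1,
            ),
            ([], 0),
            # hemizygous P counts one allele
            ([vc("GX", "c.1A>G", "P", "hemi")], 1),
            # benign classes are inert
            (
                [
                    vc("G1", "c.1A>G", "B", "hom"),
                    vc("G1", "c.2A>G", "LB", "het"),
                ],
                0,
            ),
        ],
    )
    def test_counts(self, variants, expected):
        assert qualifying_allele_count(variants) == expected

    def test_mixed_genes_rejected(self):
        with pytest.raises(ContractViolation):
            qualifying_allele_count(
                [vc("A", "c.1A>G", "P", "het"), vc("B", "c.2A>G", "P", "het")]
            )


class TestClassifyGenetic:
    def test_compound_het_with_vus_is_negative(self, table3, table3_panel):
        # one P allele plus a VUS second allele does not satisfy the AR rule
        p18 = next(s for s in table3 if s.subject_id == "P18")
        assert classify_genetic(p18.genotype, table3_panel).call == "negative"

    def test_off_panel_gene_never_triggers(self, table3, table3_panel):
        p23 = next(s for s in table3 if s.subject_id == "P23")
        res = classify_genetic(p23.genotype, table3_panel)
        assert res.call == "negative"
        assert "ETFA" in res.reason

    def test_homozygous_p_positive(self, table3, table3_panel):
        p6 = next(s for s in table3 if s.subject_id == "P6")
        res = classify_genetic(p6.genotype, table3_panel)
        assert res.call == "positive"
        assert res.qualifying_alleles == 2
        assert res.triggering_gene == "MMACHC"

    def test_no_variants_negative(self, table3_panel):
        rec = GenotypeRecord("empty", Sex.F, ())
        assert classify_genetic(rec, table3_panel).call == "negative"

    def test_hemizygous_female_rejected(self):
        rec = GenotypeRecord(
            "bad", Sex.F, (vc("GX", "c.1A>G", "P", "hemi"),)
        )
        with pytest.raises(ValidationError):
            classify_genetic(rec, XL_PANEL)

    def test_xl_male_single_allele_positive(self):
        rec = GenotypeRecord("m", Sex.M, (vc("GX", "c.1A>G", "LP", "hemi"),))
        assert classify_genetic(rec, XL_PANEL).call == "positive"

    def test_xl_female_het_negative_hom_positive(self):
        het = GenotypeRecord("f1", Sex.F, (vc("GX", "c.1A>G", "P", "het"),))
        hom = GenotypeRecord("f2", Sex.F, (vc("GX", "c.1A>G", "P", "hom"),))
        assert classify_genetic(het, XL_PANEL).call == "negative"
        assert classify_genetic(hom, XL_PANEL).call == "positive"

    def test_xl_female_het_flag_override(self):
        panel = {"GX": GeneSpec("GX", Inheritance.XL, xl_het_female_positive=True)}
        het = GenotypeRecord("f1", Sex.F, (vc("GX", "c.1A>G", "P", "het"),))
        assert classify_genetic(het, panel).call == "positive"

    def test_multi_gene_positive_reports_first_lexicographic(self):
        panel = {
            "AAA": GeneSpec("AAA", Inheritance.AR),
            "ZZZ": GeneSpec("ZZZ", Inheritance.AR),
        }
        rec = GenotypeRecord(
            "s",
            Sex.F,
            (
                vc("ZZZ", "c.1A>G", "P", "hom"),
                vc("AAA", "c.2A>G", "LP", "hom"),
            ),
        )
        res = classify_genetic(rec, panel)
        assert res.triggering_gene == "AAA"
        assert "ZZZ" in res.reason and "AAA" in res.reason


class TestCohort:
    def test_diagnosed_fixture_split(self, table3, table3_panel):
        """The 23 diagnosed subjects split 17 genetic-positive (P1-P17) /
        6 negative (P18-P23)."""
        result = classify_cohort_genetic(
            [s.genotype for s in table3], table3_panel
        )
        assert result.n_positive == 17
        for s, r in zip(table3, result):
            assert r.call == s.genetic_call, s.subject_id

    def test_empty_cohort(self, table3_panel):
        result = classify_cohort_genetic([], table3_panel)
        assert len(result) == 0 and result.n_positive == 0

    def test_duplicate_subjects_rejected(self, table3_panel):
        rec = GenotypeRecord("dup", Sex.F, ())
        with pytest.raises(ValidationError):
            classify_cohort_genetic([rec, rec], table3_panel)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence


def oracle_ar_positive(variants):
    """Direct statement of the AR rule: hom P/LP, or two distinct het P/LP."""
    qual = [v for v in variants if v.acmg_class in (AcmgClass.P, AcmgClass.LP)]
    if any(v.zygosity is Zygosity.hom for v in qual):
        return True
    return len([v for v in qual if v.zygosity is Zygosity.het]) >= 2


def oracle_xl_male_positive(variants):
    return any(
        v.acmg_class in (AcmgClass.P, AcmgClass.LP) for v in variants
    )


def _enumerate_genotypes(classes, zygosities, max_variants=3):
    for n in range(max_variants + 1):
        for combo in itertools.product(
            itertools.product(classes, zygosities), repeat=n
        ):
            yield [
                vc("G1", f"c.{i + 1}A>G", k, z) for i, (k, z) in enumerate(combo)
            ]


def test_ar_rule_matches_exhaustive_enumeration():
    """Every genotype of <=3 variants over {P,LP,VUS} x {het,hom} gets the
    same AR verdict as the explicit rule statement."""
    for variants in _enumerate_genotypes(
        [AcmgClass.P, AcmgClass.LP, AcmgClass.VUS], [Zygosity.het, Zygosity.hom]
    ):
        rec = GenotypeRecord("s", Sex.F, tuple(variants))
        got = classify_genetic(rec, AR_PANEL).call == "positive"
        assert got == oracle_ar_positive(variants), variants


def test_xl_male_rule_matches_exhaustive_enumeration():
    panel = {"G1": GeneSpec("G1", Inheritance.XL)}
    for variants in _enumerate_genotypes(
        [AcmgClass.P, AcmgClass.LP, AcmgClass.VUS], [Zygosity.het, Zygosity.hemi]
    ):
        rec = GenotypeRecord("s", Sex.M, tuple(variants))
        got = classify_genetic(rec, panel).call == "positive"
        assert got == oracle_xl_male_positive(variants), variants


# ---------------------------------------------------------------------------
# properties

_variant_st = st.builds(
    vc,
    st.just("G1"),
    st.sampled_from([f"c.{i}A>G" for i in range(1, 6)]),
    st.sampled_from([AcmgClass.P, AcmgClass.LP, AcmgClass.VUS, AcmgClass.LB, AcmgClass.B]),
    st.sampled_from([Zygosity.het, Zygosity.hom]),
)


def _record_st():
    return st.lists(_variant_st, max_size=4).map(
        lambda vs: GenotypeRecord(
            "s",
            Sex.F,
            tuple({v.variant_id: v for v in vs}.values()),
        )
    )


@settings(max_examples=200, derandomize=True)
@given(_record_st(), st.integers(min_value=0, max_value=3))
def test_class_upgrade_never_flips_positive_to_negative(record, idx):
    """Moving any variant up the B -> LB -> VUS -> LP -> P ladder can only
    make the call more positive."""
    if not record.variants:
        return
    idx = idx % len(record.variants)
    before = classify_genetic(record, AR_PANEL).call
    v = record.variants[idx]
    rank = ACMG_ORDER.index(v.acmg_class)
    if rank == len(ACMG_ORDER) - 1:
        return
    upgraded = VariantCall(
        v.gene_symbol, v.variant_id, ACMG_ORDER[rank + 1], v.zygosity
    )
    variants = list(record.variants)
    variants[idx] = upgraded
    after = classify_genetic(
        GenotypeRecord(record.subject_id, record.sex, tuple(variants)), AR_PANEL
    ).call
    assert not (before == "positive" and after == "negative")


@settings(max_examples=200, derandomize=True)
@given(_record_st(), st.integers(min_value=0, max_value=3))
def test_removing_variant_never_flips_negative_to_positive(record, idx):
    if not record.variants:
        return
    idx = idx % len(record.variants)
    before = classify_genetic(record, AR_PANEL).call
    variants = list(record.variants)
    del variants[idx]
    after = classify_genetic(
        GenotypeRecord(record.subject_id, record.sex, tuple(variants)), AR_PANEL
    ).call
    assert not (before == "negative" and after == "positive")
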