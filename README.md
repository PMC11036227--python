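# nbs-dualscreen

Analysis toolkit for **dual-modality newborn screening** of inborn errors of
metabolism (IEMs): next-generation-sequencing (NGS) gene-panel screening run
alongside conventional tandem-mass-spectrometry (MS/MS) screening of dried
blood spots, as practised in multicenter newborn-screening programmes.

It is written for screening-programme analysts and methods researchers who
need to (a) call screen positivity from variant tables and analyte profiles
with explicit, testable rules, (b) evaluate and compare the two modalities
with the field's metric conventions, (c) estimate carrier frequencies and
project disease incidence, and (d) stress-test the whole workflow on
simulated cohorts when subject-level data cannot be shared.

## What it computes

**Genotype-based screen positivity.** A subject screens positive for a gene
when pathogenic (P) or likely pathogenic (LP) variants match the gene's
inheritance pattern, judged without phenotype knowledge:

- autosomal recessive: homozygous P/LP, or two distinct heterozygous P/LP
  variants (assumed *in trans*; phase is unobserved in singleton newborn
  sequencing);
- X-linked, male: any single P/LP allele;
- X-linked, female: homozygous only (configurable per gene).

Variants of uncertain significance (VUS) never qualify, even beside a P
allele, and off-panel genes never trigger.

**MS/MS cutoff positivity.** Direction-aware, per-center thresholds over a
registry of 11 amino acids, 30 acylcarnitines, free carnitine (C0),
succinylacetone and diagnostic ratios (C3/C2, Phe/Tyr, C4/C3, C8/C10, ...).
A marker is abnormal strictly above a *high* cutoff or strictly below a
*low* cutoff (C0 and methionine are low-direction); one abnormal marker
makes the screen positive.

**Workflow and metrics.** Subjects positive by either modality are referred;
genetic positives are always recalled while MS/MS-only positives suffer
recall attrition. Per-modality confusion labels feed the screening metrics
with their programme conventions:

- PPV = confirmed / **recalled** positives (positives lost to recall have
  unknown outcomes and leave the denominator),
- sensitivity = TP / (TP + FN), recall rate = recalled / positive,
- incidence and carrier frequency rendered "1 in N".

**Population genetics.** Carrier frequencies (unaffected P/LP heterozygotes)
per gene, hotspot variant spectra with per-center breakdowns, and
Hardy–Weinberg incidence projection from carrier frequency c: with allele
frequency q, c = 2q(1−q) and incidence q², using either the rare-disease
approximation q ≈ c/2 or the exact inversion q = (1 − √(1 − 2c))/2.

**Cohort simulator.** A seeded generator producing newborn cohorts with
Hardy–Weinberg genotypes at configured carrier frequencies, variant
catalogues, biochemically silent genotype-positives, attenuated true cases
missed by MS/MS, VUS-reported true cases missed by the gene panel, one
off-panel disease gene, a calibrated background MS/MS false-positive rate,
and per-center recall attrition — so that every downstream stage has ground
truth. See `docs/methods.md` for the model and its limits.

The package also ships transcribed summary tables from a 29,601-newborn,
eight-center screening study (23 diagnosed subjects with genotypes, analyte
values and per-case cutoffs; per-center screening counts; per-disease
incidence and carrier frequencies) as validated fixtures.

## Worked example

```python
from nbs_dualscreen import fixtures
from nbs_dualscreen.screen_rules import classify_cohort_genetic
from nbs_dualscreen.pipeline import run_fixture_pipeline

subjects = fixtures.load_table3()          # the 23 diagnosed newborns
panel = fixtures.table3_panel()

result = classify_cohort_genetic([s.genotype for s in subjects], panel)
print(result.n_positive)                   # -> 17

summary = run_fixture_pipeline().summary
print(summary["incidence_one_in"])         # -> 1287
print(summary["msms"])                     # -> {'ppv': 5.29, 'sensitivity': 91.3,
                                           #     'recall_rate': 78.3, 'positive_rate': 1.71,
                                           #     'false_positives': 376, 'false_negatives': 2}
print(summary["ngs"])                      # -> {'ppv': 70.83, 'sensitivity': 73.91,
                                           #     'recall_rate': 100.0, 'positive_rate': 0.08,
                                           #     'false_positives': 7, 'false_negatives': 6}
```

Reading: among 29,601 screened newborns, 23 IEM diagnoses (1 in 1287). MS/MS
screening alone is sensitive (91.3%, missing two attenuated cases) but
unspecific (PPV 5.29%, 376 false positives among 397 recalled); gene-panel
screening is specific (PPV 70.83%, 7 biochemically silent false positives)
but less sensitive (73.91%, missing six subjects whose reports carried a VUS
or an off-panel gene). The two modalities are complementary.

The same pipeline runs on simulated cohorts:

```bash
nbs-dualscreen run --mode simulate --n 29601 --seed 11 --out report/
nbs-dualscreen simulate --n 29601 --seed 7 --out sim/
nbs-dualscreen screen-genetic --variants sim/variants.tsv --panel panel.tsv --out calls.tsv
```

## Layout

- `src/nbs_dualscreen/screen_rules.py` — genotype positivity classifier
- `src/nbs_dualscreen/msms_rules.py` — analyte cutoff classifier + registry
- `src/nbs_dualscreen/workflow.py` — referral, recall attrition, labelling
- `src/nbs_dualscreen/metrics.py` — PPV, sensitivity, recall rate, incidence
- `src/nbs_dualscreen/popgen.py` — carrier frequencies, HW projection, spectra
- `src/nbs_dualscreen/synthetic_cohort.py` — seeded cohort simulator
- `src/nbs_dualscreen/fixtures.py`, `data/` — transcribed study tables
- `src/nbs_dualscreen/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, TSV I/O
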