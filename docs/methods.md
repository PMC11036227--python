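# Methods

## Screening model

Two screens run on the same dried blood spot. The **gene-panel screen**
reports positive when a subject's variant calls satisfy the gene's
inheritance pattern using only pathogenic (P) and likely pathogenic (LP)
ACMG classes: autosomal-recessive (AR) genes require a homozygous P/LP
call or two distinct heterozygous P/LP variants; X-linked genes require a
single P/LP allele in males and a homozygous genotype in females. Three
deliberate conventions, each forced by how screening programmes operate:

- **Phase is unobserved.** Two distinct het P/LP variants in one AR gene
  are assumed *in trans*. Singleton newborn sequencing cannot phase, and
  programmes report such compound heterozygotes as positive; trio phasing
  is out of scope.
- **VUS never qualifies**, even paired with a P allele. Screening is
  performed without phenotype knowledge, so uncertain variants cannot be
  promoted by biochemistry; cases whose second allele is a VUS are
  genotype-screen negative by design and are caught, if at all, by MS/MS.
- **X-linked heterozygous females are negative** by default; a per-gene
  flag (`GeneSpec.xl_het_female_positive`) widens the rule for genes where
  a programme chooses to report manifesting carriers.

The **MS/MS screen** compares marker values against center-specific
cutoffs with a declared direction. Comparison is strict: a value exactly
at the cutoff is normal. The convention is arbitrary but fixed; the
transcribed study cases are consistent with either choice (the closest
call, C3 = 4.4 against a 4.5 cutoff, is below the threshold). One abnormal
marker suffices for positivity; disease-to-marker maps are reporting
metadata only. The marker registry defaults C0 (free carnitine) and
methionine to *low* direction — carnitine-uptake defects and cobalamin
remethylation disorders deplete them — and every other marker, including
citrulline and all ratios, to *high*. Elevated citrulline is the
citrin-deficiency/citrullinemia signal; a depressed value is normal for
screening purposes, which is why a neonate whose citrulline has not yet
risen can be missed by MS/MS and caught by genotype.

Units are per-marker metadata: a value is compared against a cutoff
declared in the same unit (mg/dL phenylalanine appears in practice);
cross-unit conversion is applied only when a factor is configured.

## Workflow and metric conventions

Referral requires at least one positive screen. Gene-panel positives are
always recalled; MS/MS-only positives are recalled with per-center
probability (attrition is a real feature of programme data). Per-modality
confusion labels: positive∧confirmed → TP; positive∧recalled∧unconfirmed →
FP; negative∧confirmed (via the other modality) → FN; otherwise TN.
Positives never recalled have unknown outcomes and are excluded from PPV.

**PPV is confirmed cases over *recalled* positives.** Many references
define PPV over all positives; programme reports use the recalled
denominator because unrecalled positives are never adjudicated. All pooled
metrics are computed from pooled counts, never by averaging per-center
percentages. Percentages round half-up with per-table decimal defaults
(published tables mix 1- and 2-decimal precision, so precision is a
parameter rather than a guess).

Incidence and carrier frequency are rendered "1 in N" with N the nearest
integer of the ratio.

## Hardy–Weinberg projection

With carrier frequency c and pathogenic allele frequency q under random
mating, c = 2q(1−q) and incidence = q². `rare` mode uses q = c/2; `exact`
mode inverts the quadratic, q = (1 − √(1 − 2c))/2 (real for c ≤ 1/2). For
c ≤ 1/40 the two differ by under 3% relative; the rare approximation is
the default because screening-panel carrier frequencies are at most a few
percent.

## Synthetic cohort generator

The generator's defaults encode the study conditions of a 29,601-newborn,
eight-center cohort; they are conditions, not tuning knobs.

| parameter | default | meaning |
|---|---|---|
| `n_newborns` | 29,601 | cohort size |
| `centers` | 8 centers, weights 4888/4813/4797/4899/2988/3006/3233/977 ÷ 29,601 | multinomial center assignment |
| per-gene `carrier_frequency` | PAH 1/42, PRODH 1/51, MMACHC 1/52, SLC25A13 1/55, SLC22A5 1/63, ACADS 1/127, ACAD8 1/211, ACADM 1/251, CPT2 1/580, MMAA 1/1139, DBT 1/1480, ETFA 1/600 | target c; allele frequency q = c/2 (rare mode) |
| `vus_allele_freq` | 1/300 per gene | background VUS carriage |
| `penetrance_biochemical` | 17/24 | probability an affected genotype is biochemically expressed (the complement models genotype-positive, biochemically silent newborns) |
| `attenuation_prob` | 2/23 | among expressed cases, probability the analytes stay within cutoffs (detectable only by genotype) |
| `vus_case_share` | 5/22 | share of affected genotypes whose second allele is *reported* as VUS (true case, genotype-screen negative) |
| `msms_fp_rate` | 0.0164 | probability a healthy newborn crosses ≥1 cutoff |
| `recall_prob` | 0.783 per center | MS/MS-only recall probability |
| `sex_ratio_male` | 0.512 | newborn sex ratio |

The off-panel mechanism is represented by one disease gene (ETFA, MADD)
configured `in_panel = false`: its cases are MS/MS-detectable but invisible
to the panel. ETFA's carrier frequency is not published for this cohort; a
value of 1/600, in the range of the study's other moderately common FAOD
genes, was chosen once. The penetrance, attenuation and VUS-share defaults
are the empirical shares observed in the study (7 silent genotype-positives
among 24 panel positives; 2 of 23 diagnosed cases MS/MS-negative; 5 of 22
on-panel cases VUS-bearing) — calibration to observed frequencies, not
estimates of biological rates. The MS/MS false-positive rate 0.0164 is
back-solved so that background positives plus detectable true cases give
an overall positive rate near 1.71%.

**Analyte model.** Healthy marker values are log-normal with fixed shape
σ = 0.35 and location solved per marker so the joint probability of
crossing any cutoff equals `msms_fp_rate`: with m cutoff markers,
p_marker = 1 − (1 − fp_rate)^(1/m) and μ = ln(threshold) ∓ z·σ with
z = Φ⁻¹(1 − p_marker) (−, high direction; +, low). Expressed,
non-attenuated cases draw their disease's primary markers strictly beyond
the cutoff (threshold × e^U(0.1, 1.2) for high, threshold × U(0.3, 0.95)
for low); attenuated and silent subjects draw every marker strictly within
its cutoff. The simulated marker panel is the default 21-marker cutoff set
covering the fixtures' markers.

**What the generator does not emulate.** Ratio markers are independent
pseudo-markers, not quotients of simulated analytes, so analyte–ratio
covariance is absent; marker–marker correlation in general is absent;
carrier counts follow Hardy–Weinberg exactly, with no founder effects or
regional allele-frequency structure (the per-center breakdown is uniform);
gestational covariates, consanguinity and CNV genotypes are not modelled;
diseased subjects missed by both screens remain unconfirmed, mirroring a
study design in which confirmation requires recall. Passing tests
therefore demonstrate the pipeline's arithmetic and rule logic under
idealised population genetics, not performance on real screening data,
where correlated analytes and founder structure move per-center numbers.

## Numerical choices

- Rounding is decimal half-up at configurable precision (string-exact
  against published tables where their precision is unambiguous).
- Metric denominators of zero raise an undefined-metric error rather than
  returning 0; batch incidence with zero cases returns a no-estimate
  marker instead.
- Variant-spectrum ties are broken lexicographically by variant id; the
  first triggering gene in lexicographic order is reported for
  multi-gene positives (all triggering genes retained in the reason).
- Simulation sizes in the test suite: parameter recovery at n = 50,000
  (three-binomial-SE check for the five headline genes), Poisson bounds
  for affected counts at n = 100,000, study-scale end-to-end runs at
  n = 29,601.
- A single integer seed drives genotype draw, analyte draw, center
  assignment and recall thinning; identical (config, seed) pairs give
  identical cohorts.

## Fixture notes

The packaged tables were transcribed with two resolved ambiguities: a
VUS second allele printed without a zygosity is recorded as heterozygous
(its class makes it inert for screening either way), and subject sex —
not printed, and irrelevant for the all-AR diagnosed cohort — is recorded
as F. Fixture loaders verify pinned SHA-256 checksums, the 23-subject
count, and that per-center totals sum to 29,601.

## Known limitations

- The genotype rule set covers AR and XL inheritance only; digenic and
  mitochondrial patterns are out of scope.
- ACMG classification itself is an input; the package never re-scores
  variants.
- Second-tier biochemistry (urine organic acids, homocysteine) enters
  only as a boolean confirmation label.
- Ratio-gating (flagging a ratio only when its primary analyte is also
  abnormal, as some centers interpret C3/C2) is available via
  `classify_msms(..., ratio_gates=...)` but off by default: ungated
  marker-level positivity is what reproduces the packaged cases, several
  of which present with a normal C3 but an elevated C3/C2.
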