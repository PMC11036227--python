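"""Synthetic newborn-cohort simulator.

Generates cohorts with the genotype and analyte structure the screening
analysis assumes, so every downstream stage is testable without patient
data. The generator emulates, with explicit knobs:

* per-gene pathogenic allele frequencies consistent with target carrier
  frequencies under Hardy-Weinberg (q = c/2 rare approximation by
  default, exact inversion available);
* autosomal-recessive and X-linked genotype formation with variant ids
  sampled from per-gene catalogues;
* biochemically silent genotype-positives (qualifying biallelic genotype,
  normal analytes, unaffected at confirmation) via
  ``penetrance_biochemical``;
* attenuated true cases whose primary markers stay within cutoffs and are
  detectable only by genotype, via ``attenuation_prob``;
* true cases reported with one VUS allele (genotype-screen negative by
  construction, MS/MS-detectable) via ``vus_case_share``;
* one off-panel disease gene, invisible to the gene panel;
* a background MS/MS false-positive rate, realised through log-normal
  healthy marker distributions whose joint tail mass beyond the cutoffs
  equals ``msms_fp_rate``;
* per-center recall attrition of MS/MS-only positives.

Healthy marker values are log-normal with a fixed shape (sigma = 0.35)
and location solved per marker so that the probability of crossing the
cutoff equals the per-marker share of the configured false-positive
rate: with m cutoff markers, p_marker = 1 - (1 - fp_rate)^(1/m), and
mu = ln(threshold) -/+ z * sigma with z the standard-normal quantile of
1 - p_marker (minus for high-direction markers, plus for low). Ratio
markers are simulated as independent pseudo-markers, not quotients.

A single seed governs all randomness; identical (config, seed) pairs
give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from nbs_dualscreen.errors import ConfigurationError, ValidationError
from nbs_dualscreen.msms_rules import (
    AnalyteProfile,
    CutoffSet,
    MarkerCutoff,
    default_direction,
)
from nbs_dualscreen.screen_rules import (
    AcmgClass,
    GeneSpec,
    GenotypeRecord,
    Inheritance,
    Sex,
    VariantCall,
    Zygosity,
    classify_genetic,
)

_LOGNORMAL_SIGMA = 0.35


@dataclass(frozen=True)
class GeneConfig:
    """Per-gene simulation parameters.

    ``carrier_frequency`` is the target c; the pathogenic allele frequency
    is q = c/2 (rare approximation) or the exact root of 2q(1-q) = c.
    ``variant_catalogue`` maps variant id → relative frequency among
    pathogenic alleles. ``primary_markers`` are the disease's MS/MS signal
    markers, shifted beyond their cutoffs in penetrant affected subjects.
    """

    gene_symbol: str
    carrier_frequency: float
    variant_catalogue: Mapping[str, float]
    primary_markers: tuple[str, ...]
    inheritance: Inheritance = Inheritance.AR
    in_panel: bool = True
    disease_name: str = ""
    vus_allele_freq: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_frequency < 1.0:
            raise ConfigurationError(
                f"{self.gene_symbol}: carrier frequency must be in [0, 1)"
            )
        if not self.variant_catalogue:
            raise ConfigurationError(f"{self.gene_symbol}: empty variant catalogue")
        total = sum(self.variant_catalogue.values())
        if total <= 0:
            raise ConfigurationError(f"{self.gene_symbol}: catalogue weights sum <= 0")
        object.__setattr__(
            self,
            "variant_catalogue",
            {k: v / total for k, v in self.variant_catalogue.items()},
        )
        object.__setattr__(self, "inheritance", Inheritance(self.inheritance))
        object.__setattr__(self, "primary_markers", tuple(self.primary_markers))

    def allele_frequency(self, mode: str = "rare") -> float:
        c = self.carrier_frequency
        if mode == "rare":
            q = c / 2.0
        else:
            if c > 0.5:
                raise ConfigurationError(
                    f"{self.gene_symbol}: 2q(1-q) = {c} has no root with q <= 1/2"
                )
            q = (1.0 - np.sqrt(1.0 - 2.0 * c)) / 2.0
        if q > 0.5:
            raise ConfigurationError(f"{self.gene_symbol}: q = {q} > 0.5")
        return q

    def to_gene_spec(self) -> GeneSpec:
        return GeneSpec(
            gene_symbol=self.gene_symbol,
            inheritance=self.inheritance,
            in_panel=self.in_panel,
            disease_name=self.disease_name,
        )


@dataclass(frozen=True)
class CohortConfig:
    n_newborns: int
    genes: tuple[GeneConfig, ...]
    centers: Mapping[str, float]
    cutoffs: CutoffSet
    seed: int = 0
    sex_ratio_male: float = 0.512
    penetrance_biochemical: float = 17.0 / 24.0
    attenuation_prob: float = 2.0 / 23.0
    vus_case_share: float = 5.0 / 22.0
    msms_fp_rate: float = 0.0164
    recall_prob: Mapping[str, float] | float = 0.783
    hw_mode: str = "rare"

    def __post_init__(self) -> None:
        if self.n_newborns < 0:
            raise ConfigurationError("n_newborns must be >= 0")
        for name, p in (
            ("sex_ratio_male", self.sex_ratio_male),
            ("penetrance_biochemical", self.penetrance_biochemical),
            ("attenuation_prob", self.attenuation_prob),
            ("vus_case_share", self.vus_case_share),
            ("msms_fp_rate", self.msms_fp_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} = {p} not in [0, 1]")
        centers = dict(self.centers)
        if not centers:
            raise ConfigurationError("at least one center required")
        total = sum(centers.values())
        if not np.isclose(total, 1.0):
            if total <= 0:
                raise ConfigurationError("center weights must sum > 0")
            centers = {k: v / total for k, v in centers.items()}
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "genes", tuple(self.genes))
        symbols = [g.gene_symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ConfigurationError("duplicate gene symbols in config")
        for g in self.genes:
            for m in g.primary_markers:
                if m not in self.cutoffs.cutoffs:
                    raise ConfigurationError(
                        f"{g.gene_symbol}: primary marker {m} lacks a cutoff"
                    )
        probs = self.recall_prob
        if isinstance(probs, Mapping):
            probs = dict(probs)
            missing = set(centers) - set(probs)
            if missing:
                raise ConfigurationError(f"recall_prob missing centers {sorted(missing)}")
            object.__setattr__(self, "recall_prob", probs)
        else:
            if not 0.0 <= probs <= 1.0:
                raise ConfigurationError("recall_prob not in [0, 1]")
            object.__setattr__(
                self, "recall_prob", {c: float(probs) for c in centers}
            )

    def panel(self) -> dict[str, GeneSpec]:
        return {g.gene_symbol: g.to_gene_spec() for g in self.genes}


@dataclass(frozen=True)
class SimulatedSubject:
    """One simulated newborn with its ground truth."""

    genotype: GenotypeRecord
    analytes: AnalyteProfile
    center_id: str
    diseased: bool  # true disease status (genotype-affected and penetrant)
    genotype_affected: bool  # biallelic/hemizygous functional genotype
    affected_gene: Optional[str] = None
    provenance: tuple[str, ...] = ()  # e.g. silent_genotype, attenuated, vus_case

    @property
    def subject_id(self) -> str:
        return self.genotype.subject_id


# ---------------------------------------------------------------------------
# default study-calibrated configuration


def default_cutoffs(center_id: str = "default") -> CutoffSet:
    """Reference cutoff set covering the simulated marker panel (µmol/L,
    ratios dimensionless)."""
    spec = {
        "C3": 4.5, "C3/C2": 0.2, "Met": 9.0, "Phe": 120.0, "Phe/Tyr": 1.5,
        "C0": 10.0, "C4": 0.46, "C4/C3": 0.4, "C8": 0.13, "C8/C10": 1.4,
        "Cit": 30.0, "Leu": 270.0, "Val": 269.0, "Pro": 400.0,
        "C5": 0.35, "C6": 0.12, "C12": 0.3, "C14": 0.4,
        "C16": 4.27, "C18": 1.8, "C18:1": 3.0,
    }
    return CutoffSet(
        center_id=center_id,
        cutoffs={
            m: MarkerCutoff(m, t, default_direction(m)) for m, t in spec.items()
        },
    )


def default_genes() -> tuple[GeneConfig, ...]:
    """The study's disease-gene panel with its observed carrier frequencies."""

    def g(symbol, c_inv, disease, markers, catalogue, in_panel=True, vus=1 / 300):
        return GeneConfig(
            gene_symbol=symbol,
            carrier_frequency=1.0 / c_inv,
            disease_name=disease,
            primary_markers=markers,
            variant_catalogue=catalogue,
            in_panel=in_panel,
            vus_allele_freq=vus,
        )

    return (
        g("PAH", 42, "PKU", ("Phe", "Phe/Tyr"),
          {"c.728G>A": 0.4, "c.721C>T": 0.3, "c.611A>G": 0.3}),
        g("PRODH", 51, "hyperprolinemia", ("Pro",),
          {"c.1322T>C": 0.6, "c.273+1G>C": 0.4}),
        g("MMACHC", 52, "cblC-MMA", ("C3", "C3/C2"),
          {"c.609G>A": 0.45, "c.658_660delAAG": 0.25, "c.482G>A": 0.18,
           "c.80A>G": 0.12}),
        g("SLC25A13", 55, "NICCD", ("Cit",),
          {"c.852_855delTATG": 0.6, "c.790G>A": 0.4}),
        g("SLC22A5", 63, "PCD", ("C0",),
          {"c.1400C>G": 0.5, "c.51C>G": 0.3, "c.760C>T": 0.1, "c.428C>T": 0.1}),
        g("ACADS", 127, "SCADD", ("C4", "C4/C3"),
          {"c.1031A>G": 0.6, "c.322G>A": 0.4}),
        g("ACAD8", 211, "IBD", ("C4",),
          {"c.289G>A": 0.5, "c.413delA": 0.5}),
        g("ACADM", 251, "MCAD", ("C8", "C8/C10"),
          {"c.946-1G>C": 0.5, "c.1085G>A": 0.5}),
        g("CPT2", 580, "CPTII", ("C16", "C18:1"),
          {"c.125C>T": 0.5, "c.1613delA": 0.5}),
        g("MMAA", 1139, "cblA-MMA", ("C3",),
          {"c.365T>C": 1.0}),
        g("DBT", 1480, "MSUD", ("Leu", "Val"),
          {"c.75_76delAT": 0.6, "c.1359_1360delAG": 0.4}),
        # off-panel disease gene: detectable only by MS/MS
        g("ETFA", 600, "MADD", ("C5", "C8"),
          {"c.369G>A": 0.5, "c.659delC": 0.5}, in_panel=False),
    )


#: Table-2-shaped center composition (fractions of the screened cohort)
DEFAULT_CENTER_WEIGHTS = {
    "SH": 4888, "GZ": 4813, "JN": 4797, "SJZ": 4899,
    "CQ": 2988, "YN": 3006, "NMG": 3233, "HN": 977,
}


def default_config(n_newborns: int = 29601, seed: int = 0) -> CohortConfig:
    """Study-calibrated cohort configuration (defaults documented in the
    methods note)."""
    return CohortConfig(
        n_newborns=n_newborns,
        genes=default_genes(),
        centers=dict(DEFAULT_CENTER_WEIGHTS),
        cutoffs=default_cutoffs(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genotype simulation


def _vus_ids(gene: GeneConfig) -> tuple[str, ...]:
    return tuple(f"c.{100 + 7 * k}A>G(VUS{k})" for k in range(1, 4))


def _draw_alleles(
    rng: np.random.Generator, n: int, q: float, v: float
) -> np.ndarray:
    """0 = reference, 1 = pathogenic, 2 = VUS."""
    u = rng.random(n)
    out = np.zeros(n, dtype=np.int8)
    out[u < q] = 1
    out[(u >= q) & (u < q + v)] = 2
    return out


def _sample_variant_ids(
    rng: np.random.Generator, gene: GeneConfig, n: int
) -> np.ndarray:
    ids = np.array(sorted(gene.variant_catalogue), dtype=object)
    probs = np.array([gene.variant_catalogue[i] for i in ids])
    return rng.choice(ids, size=n, p=probs)


@dataclass(frozen=True)
class _GenotypeTruth:
    """Per-subject functional ground truth, before ACMG-report artifacts."""

    affected: np.ndarray  # bool (n,)
    affected_gene: list  # per-subject gene symbol or None
    vus_case: np.ndarray  # bool: affected but one allele reported VUS


def _simulate_genotypes(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[GenotypeRecord], _GenotypeTruth]:
    n = config.n_newborns
    sexes = np.where(rng.random(n) < config.sex_ratio_male, "M", "F")
    per_subject: list[list[VariantCall]] = [[] for _ in range(n)]
    affected = np.zeros(n, dtype=bool)
    vus_case = np.zeros(n, dtype=bool)
    affected_gene: list = [None] * n

    for gene in config.genes:
        q = gene.allele_frequency(config.hw_mode)
        v = gene.vus_allele_freq
        if gene.inheritance is Inheritance.AR:
            a1 = _draw_alleles(rng, n, q, v)
            a2 = _draw_alleles(rng, n, q, v)
        else:  # XL: one allele for males, two for females
            a1 = _draw_alleles(rng, n, q, v)
            a2 = _draw_alleles(rng, n, q, v)
            a2[sexes == "M"] = 0

        gene_affected = (
            (a1 == 1) & (a2 == 1)
            if gene.inheritance is Inheritance.AR
            else ((a1 == 1) & ((a2 == 1) | (sexes == "M")))
        )
        # among affected genotypes, a config share has its second allele
        # reported as VUS (true case, genotype-screen negative)
        reported_vus = gene_affected & (rng.random(n) < config.vus_case_share)

        carriers = np.nonzero((a1 > 0) | (a2 > 0))[0]
        n_path = int(((a1 == 1).sum() + (a2 == 1).sum()))
        path_ids = iter(_sample_variant_ids(rng, gene, n_path))
        vus_ids = _vus_ids(gene)

        for idx in carriers:
            calls: dict[str, tuple[AcmgClass, Zygosity]] = {}
            male_xl = gene.inheritance is Inheritance.XL and sexes[idx] == "M"
            alleles = [a1[idx]] if male_xl else [a1[idx], a2[idx]]
            ids_here: list[tuple[str, AcmgClass]] = []
            for a in alleles:
                if a == 1:
                    ids_here.append((str(next(path_ids)), AcmgClass.P))
                elif a == 2:
                    vid = vus_ids[int(rng.integers(len(vus_ids)))]
                    ids_here.append((vid, AcmgClass.VUS))
            if reported_vus[idx] and len(ids_here) >= 2:
                vid, _ = ids_here[-1]
                # distinct id so the VUS allele never merges into a hom call
                ids_here[-1] = (vid + "(reclassVUS)", AcmgClass.VUS)
            for vid, klass in ids_here:
                if vid in calls and calls[vid][0] is klass:
                    calls[vid] = (klass, Zygosity.hom)
                else:
                    calls[vid] = (
                        klass,
                        Zygosity.hemi if male_xl else Zygosity.het,
                    )
            for vid, (klass, zyg) in calls.items():
                per_subject[idx].append(
                    VariantCall(gene.gene_symbol, vid, klass, zyg)
                )
            if gene_affected[idx] and not affected[idx]:
                affected[idx] = True
                affected_gene[idx] = gene.gene_symbol
            if reported_vus[idx]:
                vus_case[idx] = True

    width = max(6, len(str(max(n, 1))))
    records = [
        GenotypeRecord(
            subject_id=f"S{str(i).zfill(width)}",
            sex=Sex(sexes[i]),
            variants=tuple(per_subject[i]),
        )
        for i in range(n)
    ]
    return records, _GenotypeTruth(affected, affected_gene, vus_case)


def simulate_genotypes(
    config: CohortConfig, seed: Optional[int] = None
) -> list[GenotypeRecord]:
    """Draw genotype records for the whole cohort (reproducible under seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records, _ = _simulate_genotypes(config, rng)
    return records


# ---------------------------------------------------------------------------
# analyte simulation


def _healthy_params(
    cutoffs: CutoffSet, fp_rate: float
) -> dict[str, tuple[float, float]]:
    """Per-marker log-normal (mu, sigma) with joint cutoff-crossing mass
    equal to fp_rate."""
    markers = sorted(cutoffs.cutoffs)
    m = len(markers)
    if fp_rate >= 1.0:
        raise ConfigurationError("msms_fp_rate must be < 1")
    p_marker = 0.0 if fp_rate == 0.0 else 1.0 - (1.0 - fp_rate) ** (1.0 / m)
    # with zero tail mass, place the distribution ~6 sigma inside the cutoff
    z = 6.0 if p_marker == 0.0 else float(norm.ppf(1.0 - p_marker))
    params = {}
    for marker in markers:
        cut = cutoffs.cutoffs[marker]
        if cut.direction == "high":
            mu = np.log(cut.threshold) - z * _LOGNORMAL_SIGMA
        else:
            mu = np.log(cut.threshold) + z * _LOGNORMAL_SIGMA
        params[marker] = (mu, _LOGNORMAL_SIGMA)
    return params


def _shifted_value(
    rng: np.random.Generator, cut: MarkerCutoff
) -> float:
    """A frankly abnormal value beyond the cutoff (penetrant disease)."""
    if cut.direction == "high":
        return cut.threshold * float(np.exp(rng.uniform(0.1, 1.2)))
    return cut.threshold * float(rng.uniform(0.3, 0.95))


def _contained_value(rng: np.random.Generator, cut: MarkerCutoff) -> float:
    """A value strictly within the cutoff (attenuated / silent disease)."""
    if cut.direction == "high":
        return cut.threshold * float(rng.uniform(0.2, 0.99))
    return cut.threshold * float(rng.uniform(1.01, 2.0))


@dataclass(frozen=True)
class _AnalyteTruth:
    penetrant: np.ndarray
    attenuated: np.ndarray


def _simulate_analytes(
    genotypes: Sequence[GenotypeRecord],
    config: CohortConfig,
    truth: _GenotypeTruth,
    rng: np.random.Generator,
) -> tuple[list[AnalyteProfile], _AnalyteTruth]:
    n = len(genotypes)
    markers = sorted(config.cutoffs.cutoffs)
    params = _healthy_params(config.cutoffs, config.msms_fp_rate)
    mus = np.array([params[m][0] for m in markers])
    sigmas = np.array([params[m][1] for m in markers])
    values = np.exp(rng.normal(mus, sigmas, size=(n, len(markers))))

    penetrant = truth.affected & (rng.random(n) < config.penetrance_biochemical)
    attenuated = penetrant & (rng.random(n) < config.attenuation_prob)

    gene_by_symbol = {g.gene_symbol: g for g in config.genes}
    col = {m: j for j, m in enumerate(markers)}
    for i in np.nonzero(truth.affected)[0]:
        gene = gene_by_symbol[truth.affected_gene[i]]
        if penetrant[i] and not attenuated[i]:
            for m in gene.primary_markers:
                values[i, col[m]] = _shifted_value(rng, config.cutoffs.cutoffs[m])
        else:
            # silent or attenuated: every marker strictly within its cutoff,
            # so the subject is detectable only through the gene panel
            for j, m in enumerate(markers):
                values[i, j] = _contained_value(rng, config.cutoffs.cutoffs[m])

    profiles = [
        AnalyteProfile(
            subject_id=genotypes[i].subject_id,
            values={m: float(values[i, col[m]]) for m in markers},
        )
        for i in range(n)
    ]
    return profiles, _AnalyteTruth(penetrant, attenuated)


def simulate_analytes(
    genotypes: Sequence[GenotypeRecord],
    config: CohortConfig,
    seed: Optional[int] = None,
) -> list[AnalyteProfile]:
    """Draw analyte profiles for pre-simulated genotypes.

    Affected status is re-derived from the reported calls (biallelic or
    hemizygous P/LP in a configured gene); use :func:`simulate_cohort` for
    the fully consistent ground-truth path, which also tracks cases whose
    reports carry a VUS allele.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    # include off-panel disease genes when reconstructing affectedness
    full_panel = {
        g.gene_symbol: GeneSpec(
            g.gene_symbol, g.inheritance, True, g.disease_name
        )
        for g in config.genes
    }
    n = len(genotypes)
    affected = np.zeros(n, dtype=bool)
    affected_gene: list = [None] * n
    for i, rec in enumerate(genotypes):
        res = classify_genetic(rec, full_panel)
        if res.positive:
            affected[i] = True
            affected_gene[i] = res.triggering_gene
    truth = _GenotypeTruth(affected, affected_gene, np.zeros(n, dtype=bool))
    profiles, _ = _simulate_analytes(genotypes, config, truth, rng)
    return profiles


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> list[SimulatedSubject]:
    """Compose genotype and analyte simulation with center assignment and
    ground-truth flags; one seed governs all randomness."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genotypes, truth = _simulate_genotypes(config, rng)
    profiles, atruth = _simulate_analytes(genotypes, config, truth, rng)

    n = config.n_newborns
    center_ids = sorted(config.centers)
    weights = np.array([config.centers[c] for c in center_ids])
    assignment = rng.choice(center_ids, size=n, p=weights) if n else np.array([])

    subjects = []
    for i in range(n):
        tags = []
        if truth.affected[i]:
            if not atruth.penetrant[i]:
                tags.append("silent_genotype")
            elif atruth.attenuated[i]:
                tags.append("attenuated")
            if truth.vus_case[i]:
                tags.append("vus_case")
        subjects.append(
            SimulatedSubject(
                genotype=genotypes[i],
                analytes=profiles[i],
                center_id=str(assignment[i]),
                diseased=bool(truth.affected[i] and atruth.penetrant[i]),
                genotype_affected=bool(truth.affected[i]),
                affected_gene=truth.affected_gene[i],
                provenance=tuple(tags),
            )
        )
    return subjects
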