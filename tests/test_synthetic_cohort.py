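"""Cohort simulator: determinism, Hardy-Weinberg calibration, analyte
tail calibration, and closure of the full pipeline on simulated data."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency, poisson

from nbs_dualscreen.errors import ConfigurationError
from nbs_dualscreen.msms_rules import classify_msms, marker_abnormal
from nbs_dualscreen.popgen import carrier_frequency
from nbs_dualscreen.screen_rules import Zygosity
from nbs_dualscreen.synthetic_cohort import (
    CohortConfig,
    GeneConfig,
    default_config,
    default_cutoffs,
    default_genes,
    simulate_analytes,
    simulate_cohort,
    simulate_genotypes,
)


def _small_config(n=2000, seed=0, **overrides):
    kwargs = dict(
        n_newborns=n,
        genes=default_genes(),
        centers={"A": 0.5, "B": 0.5},
        cutoffs=default_cutoffs(),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


class TestConfigValidation:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigurationError):
            _small_config(msms_fp_rate=1.5)

    def test_center_weights_normalised(self):
        cfg = _small_config(centers={"A": 2.0, "B": 2.0})
        assert cfg.centers == {"A": 0.5, "B": 0.5}

    def test_primary_marker_needs_cutoff(self):
        gene = GeneConfig(
            "XYZ1", 0.01, {"c.1A>G": 1.0}, ("C5DC",)  # no C5DC cutoff configured
        )
        with pytest.raises(ConfigurationError):
            _small_config(genes=(gene,))

    def test_carrier_frequency_above_half_rejected(self):
        gene = GeneConfig("XYZ1", 0.9, {"c.1A>G": 1.0}, ("C3",))
        with pytest.raises(ConfigurationError):
            gene.allele_frequency("exact")


class TestSimulateGenotypes:
    def test_zero_frequency_means_no_variants(self):
        genes = tuple(
            GeneConfig(
                g.gene_symbol, 0.0, dict(g.variant_catalogue), g.primary_markers,
                vus_allele_freq=0.0,
            )
            for g in default_genes()
        )
        records = simulate_genotypes(_small_config(n=500, genes=genes))
        assert all(not r.variants for r in records)

    def test_deterministic_under_seed(self):
        cfg = _small_config(seed=3)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert a == b

    def test_distinct_seeds_differ(self):
        a = simulate_genotypes(_small_config(seed=1, n=5000))
        b = simulate_genotypes(_small_config(seed=2, n=5000))
        assert a != b

    def test_carrier_count_within_3se_of_target(self):
        """PAH carriers at n = 100,000 land within 3 binomial SE of the
        configured 1/42 carrier frequency."""
        n = 100_000
        cfg = _small_config(n=n, seed=5)
        records = simulate_genotypes(cfg)
        panel = cfg.panel()
        est = carrier_frequency(records, "PAH", panel)
        c = 1 / 42
        se = math.sqrt(c * (1 - c) / n)
        assert abs(est.carrier_frequency - c) <= 3 * se

    def test_affected_count_within_poisson_bounds(self):
        """PAH biallelic genotypes at n = 100,000 fall in the Poisson 99%
        interval around n * q^2."""
        n = 100_000
        cfg = _small_config(n=n, seed=5)
        records = simulate_genotypes(cfg)
        q = 1 / 84  # rare approximation of c = 1/42
        n_affected = sum(
            1
            for r in records
            if sum(
                2 if v.zygosity is Zygosity.hom else 1
                for v in r.variants_in_gene("PAH")
                if v.acmg_class.value in ("P", "LP")
            )
            >= 2
        )
        lam = n * q * q
        lo, hi = poisson.ppf(0.005, lam), poisson.ppf(0.995, lam)
        assert lo <= n_affected <= hi

    def test_seeds_statistically_indistinguishable(self):
        """Across 10 seeds, PAH carrier counts are homogeneous (chi-square
        test at alpha = 0.01)."""
        n = 20_000
        counts = []
        for seed in range(10):
            cfg = _small_config(n=n, seed=seed)
            est = carrier_frequency(
                simulate_genotypes(cfg), "PAH", cfg.panel()
            )
            counts.append(est.n_carriers)
        table = np.array([counts, [n - c for c in counts]])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01


class TestSimulateAnalytes:
    def test_zero_fp_rate_no_healthy_positive(self):
        cfg = _small_config(n=1000, msms_fp_rate=0.0)
        subjects = simulate_cohort(cfg)
        healthy = [s for s in subjects if not s.genotype_affected]
        for s in healthy:
            res = classify_msms(s.analytes, cfg.cutoffs)
            assert res.call == "negative", s.subject_id

    def test_full_penetrance_no_attenuation_all_affected_positive(self):
        cfg = _small_config(
            n=30_000, seed=9, penetrance_biochemical=1.0, attenuation_prob=0.0
        )
        subjects = simulate_cohort(cfg)
        affected = [s for s in subjects if s.genotype_affected]
        assert affected, "expected some affected genotypes at this n"
        for s in affected:
            assert classify_msms(s.analytes, cfg.cutoffs).call == "positive"

    def test_background_positive_rate_near_configured(self):
        """At study scale the overall MS/MS positive rate lands near the
        configured 1.71% (background false positives plus true cases)."""
        cfg = default_config(n_newborns=29601, seed=4)
        subjects = simulate_cohort(cfg)
        n_pos = sum(
            classify_msms(s.analytes, cfg.cutoffs).positive for s in subjects
        )
        rate = n_pos / len(subjects)
        # Monte-Carlo tolerance: 4 binomial SE of the target rate
        target = 0.0171
        se = math.sqrt(target * (1 - target) / len(subjects))
        assert abs(rate - target) <= 4 * se

    def test_simulate_analytes_standalone_is_reproducible(self):
        cfg = _small_config(n=500, seed=12)
        genotypes = simulate_genotypes(cfg)
        a = simulate_analytes(genotypes, cfg)
        b = simulate_analytes(genotypes, cfg)
        assert a == b


class TestSimulateCohort:
    def test_identical_seed_identical_cohort(self):
        cfg = _small_config(n=1500, seed=21)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_empty_cohort(self):
        assert simulate_cohort(_small_config(n=0)) == []

    def test_center_assignment_respects_weights(self):
        cfg = _small_config(n=10_000, centers={"A": 0.8, "B": 0.2}, seed=2)
        subjects = simulate_cohort(cfg)
        share_a = sum(s.center_id == "A" for s in subjects) / len(subjects)
        assert abs(share_a - 0.8) < 0.02

    def test_ground_truth_consistency(self):
        cfg = _small_config(n=30_000, seed=8)
        subjects = simulate_cohort(cfg)
        for s in subjects:
            if s.diseased:
                assert s.genotype_affected and s.affected_gene is not None
            if "silent_genotype" in s.provenance:
                assert s.genotype_affected and not s.diseased

    def test_headline_carrier_recovery(self):
        """The five most carrier-heavy genes recover their configured
        frequencies within 3 binomial SE at n = 50,000."""
        n = 50_000
        cfg = _small_config(n=n, seed=17)
        records = [s.genotype for s in simulate_cohort(cfg)]
        panel = cfg.panel()
        targets = {
            "PAH": 1 / 42, "PRODH": 1 / 51, "MMACHC": 1 / 52,
            "SLC25A13": 1 / 55, "SLC22A5": 1 / 63,
        }
        for gene, c in targets.items():
            est = carrier_frequency(records, gene, panel)
            se = math.sqrt(c * (1 - c) / n)
            assert abs(est.carrier_frequency - c) <= 3 * se, gene
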