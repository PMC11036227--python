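"""End-to-end pipeline: screen → workflow → metrics → population genetics.

Two modes:

* **fixture mode** runs both classifiers on the 23 packaged diagnosed-
  subject records and derives the screening-performance report from the
  packaged per-center count table (per-modality false positives and
  recall attrition are only published as aggregates, so fixture-mode
  metrics come from those printed counts);
* **simulate mode** generates a synthetic cohort, screens every subject
  with both modalities, applies recall attrition, labels outcomes against
  simulated ground truth, and computes the same report shape plus
  carrier-frequency estimates with Hardy-Weinberg incidence projections.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np

from nbs_dualscreen import fixtures, io
from nbs_dualscreen.errors import ConfigurationError
from nbs_dualscreen.metrics import (
    PerformanceRow,
    build_performance_table,
    incidence,
    performance_from_counts,
    positive_rate,
    ppv,
    recall_rate,
    sensitivity,
)
from nbs_dualscreen.msms_rules import classify_msms
from nbs_dualscreen.popgen import carrier_frequency, hw_project_incidence
from nbs_dualscreen.screen_rules import classify_cohort_genetic, classify_genetic
from nbs_dualscreen.synthetic_cohort import (
    CohortConfig,
    SimulatedSubject,
    default_config,
    simulate_cohort,
)
from nbs_dualscreen.workflow import (
    DiagnosisRecord,
    SubjectOutcome,
    apply_recall,
    label_outcomes,
)

log = logging.getLogger("nbs_dualscreen")


@dataclass
class ReportBundle:
    """Computed report plus the tables behind it."""

    mode: str
    summary: dict[str, Any]
    msms_table: list[PerformanceRow] = field(default_factory=list)
    ngs_table: list[PerformanceRow] = field(default_factory=list)
    outcomes: list[SubjectOutcome] = field(default_factory=list)
    popgen: list[dict[str, Any]] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.summary, indent=2, default=str) + "\n"
        )
        for name, table in (("msms", self.msms_table), ("ngs", self.ngs_table)):
            if table:
                _write_performance_tsv(table, out / f"performance_{name}.tsv")
        if self.outcomes:
            io.write_outcome_table(self.outcomes, out / "outcomes.tsv")
        if self.popgen:
            import pandas as pd

            pd.DataFrame(self.popgen).to_csv(
                out / "carrier_frequencies.tsv", sep="\t", index=False
            )


def _write_performance_tsv(rows: Sequence[PerformanceRow], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "center": r.center_id,
                "n_screened": r.n_screened,
                "n_positive": r.n_positive,
                "n_recalled": r.n_recalled,
                "recall_rate": r.recall_rate,
                "n_confirmed": r.n_confirmed,
                "ppv": r.ppv,
                "n_false_negative": r.n_false_negative,
                "sensitivity": "" if r.sensitivity is None else r.sensitivity,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fixture mode


def fixture_performance_tables() -> tuple[list[PerformanceRow], list[PerformanceRow]]:
    """Per-center + pooled performance rows from the packaged count table."""
    counts = fixtures.load_table2()
    msms_rows, ngs_rows = [], []
    t = dict.fromkeys(
        ("n", "mp", "mr", "mc", "mf", "gp", "gr", "gc", "gf"), 0
    )
    for c in counts:
        msms_rows.append(
            performance_from_counts(
                c.center, c.n_screened, c.msms_positive, c.msms_recalled,
                c.msms_confirmed, c.msms_false_negative,
            )
        )
        ngs_rows.append(
            performance_from_counts(
                c.center, c.n_screened, c.ngs_positive, c.ngs_recalled,
                c.ngs_confirmed, c.ngs_false_negative,
            )
        )
        t["n"] += c.n_screened
        t["mp"] += c.msms_positive; t["mr"] += c.msms_recalled
        t["mc"] += c.msms_confirmed; t["mf"] += c.msms_false_negative
        t["gp"] += c.ngs_positive; t["gr"] += c.ngs_recalled
        t["gc"] += c.ngs_confirmed; t["gf"] += c.ngs_false_negative
    msms_rows.append(
        performance_from_counts("Total", t["n"], t["mp"], t["mr"], t["mc"], t["mf"])
    )
    ngs_rows.append(
        performance_from_counts("Total", t["n"], t["gp"], t["gr"], t["gc"], t["gf"])
    )
    return msms_rows, ngs_rows


def run_fixture_pipeline() -> ReportBundle:
    """Classify the 23 diagnosed subjects and reproduce the study report."""
    t0 = time.perf_counter()
    subjects = fixtures.load_table3()
    panel = fixtures.table3_panel()

    genetic = classify_cohort_genetic([s.genotype for s in subjects], panel)
    msms = [
        classify_msms(s.primary_profile, s.primary_cutoffs) for s in subjects
    ]
    log.info("classified %d fixture subjects", len(subjects))

    msms_table, ngs_table = fixture_performance_tables()
    msms_total, ngs_total = msms_table[-1], ngs_table[-1]

    overall = incidence(23, fixtures.N_SCREENED)
    summary = {
        "mode": "fixtures",
        "n_screened": fixtures.N_SCREENED,
        "n_diagnosed": 23,
        "incidence_one_in": overall.reciprocal,
        "genetic_fixture_positives": genetic.n_positive,
        "msms_fixture_positives": sum(r.positive for r in msms),
        "msms": {
            "ppv": msms_total.ppv,
            "sensitivity": msms_total.sensitivity,
            "recall_rate": msms_total.recall_rate,
            "positive_rate": positive_rate(
                msms_total.n_positive, msms_total.n_screened
            ),
            "false_positives": msms_total.n_recalled - msms_total.n_confirmed,
            "false_negatives": msms_total.n_false_negative,
        },
        "ngs": {
            "ppv": ngs_total.ppv,
            "sensitivity": ngs_total.sensitivity,
            "recall_rate": ngs_total.recall_rate,
            "positive_rate": positive_rate(
                ngs_total.n_positive, ngs_total.n_screened
            ),
            "false_positives": ngs_total.n_recalled - ngs_total.n_confirmed,
            "false_negatives": ngs_total.n_false_negative,
        },
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return ReportBundle(
        mode="fixtures",
        summary=summary,
        msms_table=msms_table,
        ngs_table=ngs_table,
        outcomes=fixtures.table3_outcomes(),
    )


# ---------------------------------------------------------------------------
# simulate mode


def evaluate_cohort(
    subjects: Sequence[SimulatedSubject],
    config: CohortConfig,
    rng: np.random.Generator | int | None = None,
) -> ReportBundle:
    """Screen, recall, label and score a simulated cohort."""
    t0 = time.perf_counter()
    panel = config.panel()
    disease_of = {g.gene_symbol: g.disease_name for g in config.genes}
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    outcomes = []
    for s in subjects:
        ngs = classify_genetic(s.genotype, panel)
        msms = classify_msms(s.analytes, config.cutoffs)
        outcomes.append(
            SubjectOutcome(
                subject_id=s.subject_id,
                center_id=s.center_id,
                ngs_call=ngs.call,
                msms_call=msms.call,
                recalled=False,  # set by apply_recall
                diagnosis=DiagnosisRecord(s.subject_id, False),
            )
        )
    outcomes = apply_recall(outcomes, config.recall_prob, rng)

    # confirmation: ground-truth disease surfaces iff the subject was recalled
    diseased = {s.subject_id: s for s in subjects if s.diseased}
    confirmed = []
    for o in outcomes:
        s = diseased.get(o.subject_id)
        if s is not None and o.recalled:
            o = SubjectOutcome(
                subject_id=o.subject_id,
                center_id=o.center_id,
                ngs_call=o.ngs_call,
                msms_call=o.msms_call,
                recalled=o.recalled,
                diagnosis=DiagnosisRecord(
                    o.subject_id, True, disease_of.get(s.affected_gene, "IEM")
                ),
            )
        confirmed.append(o)
    outcomes = label_outcomes(confirmed)

    msms_table = build_performance_table(outcomes, "msms")
    ngs_table = build_performance_table(outcomes, "ngs")
    msms_total, ngs_total = msms_table[-1], ngs_table[-1]

    genotypes = [s.genotype for s in subjects]
    pop_rows = []
    for g in config.genes:
        est = carrier_frequency(genotypes, g.gene_symbol, panel)
        row: dict[str, Any] = {
            "gene": g.gene_symbol,
            "n_carriers": est.n_carriers,
            "n": est.n_screened,
            "carrier_freq": est.carrier_frequency,
            "carrier_one_in": est.one_in_n,
            "configured_one_in": round(1.0 / g.carrier_frequency),
        }
        if est.n_carriers > 0:
            proj = hw_project_incidence(est.carrier_frequency, "rare", g.gene_symbol)
            row["hw_incidence_one_in"] = proj.one_in_n
        pop_rows.append(row)

    n_confirmed_total = sum(o.diagnosis.confirmed for o in outcomes)
    overall = incidence(n_confirmed_total, len(subjects)) if subjects else None
    summary = {
        "mode": "simulate",
        "seed": config.seed,
        "n_screened": len(subjects),
        "n_diagnosed": n_confirmed_total,
        "incidence_one_in": overall.reciprocal if overall else None,
        "msms": {
            "ppv": msms_total.ppv,
            "sensitivity": msms_total.sensitivity,
            "recall_rate": msms_total.recall_rate,
            "positive_rate": positive_rate(msms_total.n_positive, len(subjects)),
        },
        "ngs": {
            "ppv": ngs_total.ppv,
            "sensitivity": ngs_total.sensitivity,
            "recall_rate": ngs_total.recall_rate,
            "positive_rate": positive_rate(ngs_total.n_positive, len(subjects)),
        },
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return ReportBundle(
        mode="simulate",
        summary=summary,
        msms_table=msms_table,
        ngs_table=ngs_table,
        outcomes=outcomes,
        popgen=pop_rows,
    )


def run_simulated_pipeline(
    config: Optional[CohortConfig] = None,
    n_newborns: int = 29601,
    seed: int = 0,
) -> ReportBundle:
    if config is None:
        config = default_config(n_newborns=n_newborns, seed=seed)
    subjects = simulate_cohort(config)
    return evaluate_cohort(subjects, config)


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> ReportBundle:
    """Umbrella entry point driven by a JSON-compatible config mapping.

    ``{"mode": "fixtures"}`` or
    ``{"mode": "simulate", "n_newborns": int, "seed": int}``.
    """
    if "mode" not in config:
        raise ConfigurationError("config must declare a mode")
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:12]
    from nbs_dualscreen import __version__

    log.info(
        "run_pipeline version=%s mode=%s seed=%s config_hash=%s",
        __version__, config["mode"], config.get("seed"), digest,
    )
    if config["mode"] == "fixtures":
        bundle = run_fixture_pipeline()
    elif config["mode"] == "simulate":
        bundle = run_simulated_pipeline(
            n_newborns=int(config.get("n_newborns", 29601)),
            seed=int(config.get("seed", 0)),
        )
    else:
        raise ConfigurationError(f"unknown mode {config['mode']!r}")
    bundle.summary["config_hash"] = digest
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
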