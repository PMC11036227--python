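"""Screening-performance metrics and incidence.

Conventions follow multicenter newborn-screening practice:

* PPV = confirmed cases / *recalled* positives (not all positives:
  screen-positives lost to recall have unknown outcomes and drop out of
  the denominator). This differs from textbook PPV over all positives and
  is the convention every per-center figure here relies on.
* Recall rate = recalled / positive; positive rate = positive / screened.
* Sensitivity = TP / (TP + FN), where FN are confirmed cases the modality
  missed but the study design could still surface.
* Incidence is reported as "1 in N" with N the nearest integer of
  screened/cases.

Percentages round half-up at a configurable number of decimals, because
published screening tables mix 1- and 2-decimal precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

from nbs_dualscreen.errors import UndefinedMetricError, ValidationError
from nbs_dualscreen.workflow import SubjectOutcome

Modality = Literal["msms", "ngs"]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ppv(n_confirmed: int, n_recalled: int, decimals: int = 2) -> float:
    """Positive predictive value in percent: 100 * confirmed / recalled."""
    if n_recalled < 1:
        raise UndefinedMetricError("PPV undefined with zero recalled positives")
    if n_confirmed > n_recalled:
        raise ValidationError("confirmed cases exceed recalled positives")
    return _round_half_up(100.0 * n_confirmed / n_recalled, decimals)


def sensitivity(n_true_positive: int, n_false_negative: int, decimals: int = 2) -> float:
    """Sensitivity in percent: 100 * TP / (TP + FN)."""
    denom = n_true_positive + n_false_negative
    if denom < 1:
        raise UndefinedMetricError("sensitivity undefined with no detectable cases")
    return _round_half_up(100.0 * n_true_positive / denom, decimals)


def recall_rate(n_recalled: int, n_positive: int, decimals: int = 1) -> float:
    """Recall rate in percent: 100 * recalled / positive."""
    if n_positive < 1:
        raise UndefinedMetricError("recall rate undefined with zero positives")
    if n_recalled > n_positive:
        raise ValidationError("recalled exceeds positives")
    return _round_half_up(100.0 * n_recalled / n_positive, decimals)


def positive_rate(n_positive: int, n_screened: int, decimals: int = 2) -> float:
    """Screen-positive rate in percent: 100 * positive / screened."""
    if n_screened < 1:
        raise UndefinedMetricError("positive rate undefined with empty cohort")
    return _round_half_up(100.0 * n_positive / n_screened, decimals)


@dataclass(frozen=True)
class IncidenceEstimate:
    disease_name: str
    n_cases: int
    n_screened: int
    reciprocal: Optional[int]  # the N of "1 in N"; None when no cases observed

    def __str__(self) -> str:
        if self.reciprocal is None:
            return f"{self.disease_name}: no cases observed"
        return f"{self.disease_name}: 1 in {self.reciprocal}"


def incidence(n_cases: int, n_screened: int, disease_name: str = "all") -> IncidenceEstimate:
    """Observed incidence as 1-in-N with N = round(screened / cases)."""
    if n_screened < 1:
        raise ValidationError("n_screened must be >= 1")
    if n_cases > n_screened:
        raise ValidationError("cases exceed screened")
    if n_cases == 0:
        return IncidenceEstimate(disease_name, 0, n_screened, None)
    return IncidenceEstimate(
        disease_name, n_cases, n_screened, round(n_screened / n_cases)
    )


@dataclass(frozen=True)
class PerformanceRow:
    """One center's counts and derived metrics (or the pooled totals row)."""

    center_id: str
    n_screened: int
    n_positive: int
    n_recalled: int
    recall_rate: float
    n_confirmed: int
    ppv: float
    n_false_negative: int
    sensitivity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_confirmed <= self.n_recalled <= self.n_positive <= self.n_screened
        ):
            raise ValidationError(
                f"{self.center_id}: counts must satisfy "
                "confirmed <= recalled <= positive <= screened"
            )


def performance_from_counts(
    center_id: str,
    n_screened: int,
    n_positive: int,
    n_recalled: int,
    n_confirmed: int,
    n_false_negative: int,
    recall_decimals: int = 1,
    ppv_decimals: int = 2,
    sens_decimals: int = 2,
) -> PerformanceRow:
    """Derive a performance row from raw counts (as printed in reports)."""
    sens = None
    if n_confirmed + n_false_negative >= 1:
        sens = sensitivity(n_confirmed, n_false_negative, sens_decimals)
    return PerformanceRow(
        center_id=center_id,
        n_screened=n_screened,
        n_positive=n_positive,
        n_recalled=n_recalled,
        recall_rate=recall_rate(n_recalled, n_positive, recall_decimals),
        n_confirmed=n_confirmed,
        ppv=ppv(n_confirmed, n_recalled, ppv_decimals),
        n_false_negative=n_false_negative,
        sensitivity=sens,
    )


def build_performance_table(
    outcomes: Sequence[SubjectOutcome],
    modality: Modality,
    recall_decimals: int = 1,
    ppv_decimals: int = 2,
) -> list[PerformanceRow]:
    """Per-center rows plus a pooled ``Total`` row from labelled outcomes.

    Totals are computed from pooled counts, never by averaging per-center
    percentages. Recall counts for a modality include only that modality's
    positives that were recalled.
    """
    if modality not in ("msms", "ngs"):
        raise ValidationError(f"unknown modality {modality!r}")
    for o in outcomes:
        if o.ngs_label is None or o.msms_label is None:
            raise ValidationError(f"{o.subject_id} is unlabelled; run label_outcomes")

    centers = sorted({o.center_id for o in outcomes})
    rows: list[PerformanceRow] = []

    def counts(subset: Sequence[SubjectOutcome]) -> tuple[int, int, int, int, int]:
        if modality == "msms":
            pos = [o for o in subset if o.msms_call == "positive"]
            labels = [o.msms_label for o in subset]
        else:
            pos = [o for o in subset if o.ngs_call == "positive"]
            labels = [o.ngs_label for o in subset]
        n_pos = len(pos)
        n_rec = sum(o.recalled for o in pos)
        n_conf = labels.count("TP")
        n_fn = labels.count("FN")
        return len(subset), n_pos, n_rec, n_conf, n_fn

    for center in centers:
        subset = [o for o in outcomes if o.center_id == center]
        n, n_pos, n_rec, n_conf, n_fn = counts(subset)
        if n_rec == 0:
            continue  # no recalled positives: PPV undefined for this center
        rows.append(
            performance_from_counts(
                center, n, n_pos, n_rec, n_conf, n_fn,
                recall_decimals=recall_decimals, ppv_decimals=ppv_decimals,
            )
        )
    n, n_pos, n_rec, n_conf, n_fn = counts(list(outcomes))
    rows.append(
        performance_from_counts(
            "Total", n, n_pos, n_rec, n_conf, n_fn,
            recall_decimals=recall_decimals, ppv_decimals=ppv_decimals,
        )
    )
    return rows
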