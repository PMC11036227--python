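"""Combined referral, recall and outcome labelling.

A newborn positive by either the gene-panel screen or the MS/MS screen is
referred for confirmatory testing. Genetic-screen positives are always
recalled (the study recalled 100% of them); MS/MS-only positives suffer
recall attrition, modelled as per-center Bernoulli thinning. Confirmed
diagnoses then yield per-modality truth labels:

* positive and confirmed            → true positive
* positive, recalled, unconfirmed   → false positive
* negative but confirmed (the other modality caught the case) → false negative
* everything else                   → true negative

Positives never recalled have unknown outcomes; they are excluded from the
PPV denominator (PPV here is confirmed cases among *recalled* positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from nbs_dualscreen.errors import ValidationError
from nbs_dualscreen.msms_rules import MsmsScreenResult
from nbs_dualscreen.screen_rules import GeneticScreenResult


@dataclass(frozen=True)
class DiagnosisRecord:
    subject_id: str
    confirmed: bool
    disease_name: Optional[str] = None
    basis: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.confirmed and not self.disease_name:
            raise ValidationError(
                f"confirmed diagnosis for {self.subject_id} requires disease_name"
            )
        allowed = {"genotype", "msms", "confirmatory_tests"}
        bad = set(self.basis) - allowed
        if bad:
            raise ValidationError(f"unknown diagnosis basis {sorted(bad)}")
        object.__setattr__(self, "basis", frozenset(self.basis))


@dataclass(frozen=True)
class SubjectOutcome:
    subject_id: str
    center_id: str
    ngs_call: str  # "positive" | "negative"
    msms_call: str
    recalled: bool
    diagnosis: DiagnosisRecord
    ngs_label: Optional[str] = None  # TP/FP/TN/FN, set by label_outcomes
    msms_label: Optional[str] = None

    def __post_init__(self) -> None:
        for call in (self.ngs_call, self.msms_call):
            if call not in ("positive", "negative"):
                raise ValidationError(f"invalid call {call!r}")
        if self.recalled and self.ngs_call == self.msms_call == "negative":
            raise ValidationError(
                f"{self.subject_id} recalled despite double-negative screen"
            )

    @property
    def referred(self) -> bool:
        return self.ngs_call == "positive" or self.msms_call == "positive"


def combine_calls(ngs: GeneticScreenResult, msms: MsmsScreenResult) -> str:
    """``refer`` iff either modality is positive; symmetric in its inputs."""
    if ngs.subject_id != msms.subject_id:
        raise ValidationError(
            f"subject mismatch: {ngs.subject_id!r} vs {msms.subject_id!r}"
        )
    return "refer" if (ngs.positive or msms.positive) else "no_refer"


def apply_recall(
    referrals: Sequence[SubjectOutcome],
    recall_probability: Mapping[str, float] | float,
    rng: np.random.Generator | int | None = None,
) -> list[SubjectOutcome]:
    """Thin MS/MS-only referrals by per-center recall probabilities.

    Genetic-screen positives are exempt from attrition and always
    recalled. Reproducible given an integer seed or a Generator.
    """
    if not isinstance(recall_probability, Mapping):
        recall_probability = {o.center_id: float(recall_probability) for o in referrals}
    for center, p in recall_probability.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"recall probability {p} for {center} not in [0,1]")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    out: list[SubjectOutcome] = []
    for o in referrals:
        if not o.referred:
            out.append(replace(o, recalled=False))
        elif o.ngs_call == "positive":
            out.append(replace(o, recalled=True))
        else:
            try:
                p = recall_probability[o.center_id]
            except KeyError:
                raise ValidationError(
                    f"no recall probability for center {o.center_id!r}"
                ) from None
            out.append(replace(o, recalled=bool(gen.random() < p)))
    return out


def _modality_label(positive: bool, recalled: bool, confirmed: bool) -> str:
    if positive and confirmed:
        return "TP"
    if positive and recalled and not confirmed:
        return "FP"
    if not positive and confirmed:
        return "FN"
    return "TN"


def label_outcomes(outcomes: Iterable[SubjectOutcome]) -> list[SubjectOutcome]:
    """Attach per-modality TP/FP/TN/FN labels.

    A subject confirmed only through the other modality's recall counts as
    a false negative for the modality that missed it. A confirmed
    diagnosis on an unreferred subject is inconsistent with the study
    design (no route to confirmation) and rejected.
    """
    labelled = []
    for o in outcomes:
        confirmed = o.diagnosis.confirmed
        if confirmed and not o.referred:
            raise ValidationError(
                f"{o.subject_id}: confirmed diagnosis without any positive screen"
            )
        labelled.append(
            replace(
                o,
                ngs_label=_modality_label(o.ngs_call == "positive", o.recalled, confirmed),
                msms_label=_modality_label(o.msms_call == "positive", o.recalled, confirmed),
            )
        )
    return labelled
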