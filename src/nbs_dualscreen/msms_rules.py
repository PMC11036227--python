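"""MS/MS analyte-cutoff screen positivity.

Tandem mass spectrometry on dried blood spots quantifies amino acids,
acylcarnitines, free carnitine (C0) and succinylacetone; diagnostic ratios
(C3/C2, Phe/Tyr, C4/C3, C8/C10, ...) serve as secondary indicators. Each
screening center declares its own reference cutoff per marker, with a
direction: a *high* marker is abnormal strictly above its threshold, a
*low* marker strictly below (a value exactly at the threshold is normal).
A profile screens positive when at least one marker is abnormal.

The marker registry covers the assayed panel — 11 amino acids, 30
acylcarnitines, free carnitine, succinylacetone — plus declared ratios.
Free carnitine (C0) and methionine are low-direction by default (carnitine
uptake defects and remethylation disorders deplete them); every other
marker, including citrulline and all ratios, defaults to high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

from nbs_dualscreen.errors import RegistryError, ValidationError

_AMINO_ACIDS = (
    "Phe", "Tyr", "Leu", "Met", "Val", "Cit", "Arg", "Orn", "Gly", "Pro", "Ala",
)
_ACYLCARNITINES = (
    "C2", "C3", "C3DC", "C4", "C5", "C5:1", "C5DC", "C5OH", "C6", "C6DC",
    "C8", "C8:1", "C10", "C10:1", "C10:2", "C12", "C12:1", "C14", "C14:1",
    "C14:2", "C14OH", "C16", "C16:1", "C16OH", "C16:1OH", "C18", "C18:1",
    "C18:2", "C18OH", "C18:1OH",
)
_SINGLES = ("C0", "SA")
_RATIOS = (
    "C3/C2", "Phe/Tyr", "C4/C3", "C8/C10", "C0/(C16+C18)", "Cit/Arg",
    "Met/Phe", "Leu/Phe", "C14:1/C2", "C5/C3", "C5DC/C8",
)

#: markers whose deficiency (not excess) is the disease signal
LOW_DIRECTION_MARKERS = frozenset({"C0", "Met"})

MARKER_REGISTRY: frozenset[str] = frozenset(
    _AMINO_ACIDS + _ACYLCARNITINES + _SINGLES + _RATIOS
)


def default_direction(marker_name: str) -> str:
    if marker_name not in MARKER_REGISTRY:
        raise RegistryError(f"unknown marker {marker_name!r}")
    return "low" if marker_name in LOW_DIRECTION_MARKERS else "high"


@dataclass(frozen=True)
class AnalyteProfile:
    """One subject's marker → value map.

    Values are µmol/L for analytes and dimensionless for ratios unless the
    paired cutoff declares another unit (mg/dL phenylalanine occurs in
    practice and is compared against a cutoff in the same unit).
    """

    subject_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = dict(self.values)
        for marker, value in vals.items():
            if marker not in MARKER_REGISTRY:
                raise RegistryError(f"unknown marker {marker!r}")
            if value < 0:
                raise ValidationError(f"{marker} value {value} is negative")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class MarkerCutoff:
    marker_name: str
    threshold: float
    direction: str = ""  # "high" | "low"; defaults from the registry
    unit: str = "umol/L"

    def __post_init__(self) -> None:
        if self.marker_name not in MARKER_REGISTRY:
            raise RegistryError(f"unknown marker {self.marker_name!r}")
        if not self.threshold > 0:
            raise ValidationError(
                f"threshold for {self.marker_name} must be > 0, got {self.threshold}"
            )
        direction = self.direction or default_direction(self.marker_name)
        if direction not in ("high", "low"):
            raise ValidationError(f"invalid direction {direction!r}")
        object.__setattr__(self, "direction", direction)


@dataclass(frozen=True)
class CutoffSet:
    """One screening center's cutoffs, one per marker."""

    center_id: str
    cutoffs: Mapping[str, MarkerCutoff]

    def __post_init__(self) -> None:
        cuts = dict(self.cutoffs)
        for marker, cut in cuts.items():
            if cut.marker_name != marker:
                raise ValidationError(
                    f"cutoff keyed {marker!r} describes {cut.marker_name!r}"
                )
        object.__setattr__(self, "cutoffs", cuts)


@dataclass(frozen=True)
class FlaggedMarker:
    marker_name: str
    value: float
    threshold: float
    direction: str


@dataclass(frozen=True)
class MsmsScreenResult:
    subject_id: str
    call: str  # "positive" | "negative"
    flagged_markers: tuple[FlaggedMarker, ...] = ()

    def __post_init__(self) -> None:
        if self.call not in ("positive", "negative"):
            raise ValidationError(f"invalid call {self.call!r}")
        if (self.call == "positive") != bool(self.flagged_markers):
            raise ValidationError("positive iff flagged_markers non-empty")

    @property
    def positive(self) -> bool:
        return self.call == "positive"


def marker_abnormal(value: float, cutoff: MarkerCutoff) -> bool:
    """Strict-inequality comparison; equality with the threshold is normal."""
    if value < 0:
        raise ValidationError(f"negative marker value {value}")
    if cutoff.direction == "high":
        return value > cutoff.threshold
    return value < cutoff.threshold


#: conventional primary analyte behind each ratio, for the optional gated rule
DEFAULT_RATIO_GATES = {
    "C3/C2": "C3",
    "Phe/Tyr": "Phe",
    "C4/C3": "C4",
    "C8/C10": "C8",
}


def classify_msms(
    profile: AnalyteProfile,
    cutoffs: CutoffSet,
    ratio_gates: Mapping[str, str] | None = None,
) -> MsmsScreenResult:
    """Positive iff at least one marker crosses its center cutoff.

    Markers in the profile without a declared cutoff are skipped with a
    warning. Flagged markers are reported sorted by marker name, so the
    result is invariant under profile iteration order.

    ``ratio_gates`` enables the stricter convention some centers use, in
    which a ratio (e.g. C3/C2) only counts when its primary analyte (C3)
    is itself abnormal; the default (None) flags ratios on their own,
    which is what reproduces the packaged study cases — several true
    cblC-MMA cases present with a normal C3 but elevated C3/C2.
    """
    if not profile.values:
        raise ValidationError(f"empty analyte profile for {profile.subject_id}")

    def abnormal(marker: str) -> Optional[MarkerCutoff]:
        cut = cutoffs.cutoffs.get(marker)
        if cut is None or marker not in profile.values:
            return None
        return cut if marker_abnormal(profile.values[marker], cut) else None

    flagged: list[FlaggedMarker] = []
    for marker in sorted(profile.values):
        cut = cutoffs.cutoffs.get(marker)
        if cut is None:
            warnings.warn(
                f"marker {marker} has no cutoff at center {cutoffs.center_id}; skipped",
                stacklevel=2,
            )
            continue
        value = profile.values[marker]
        if not marker_abnormal(value, cut):
            continue
        if ratio_gates is not None and marker in ratio_gates:
            if abnormal(ratio_gates[marker]) is None:
                continue  # ratio suppressed: its primary analyte is normal
        flagged.append(FlaggedMarker(marker, value, cut.threshold, cut.direction))
    call = "positive" if flagged else "negative"
    return MsmsScreenResult(
        subject_id=profile.subject_id, call=call, flagged_markers=tuple(flagged)
    )
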