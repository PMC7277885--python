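"""Modified Index of Caring Dependence (mICD) scoring.

Eight nursing care dimensions -- nutrition/hydration, elimination,
hygiene/comfort, mobilization, diagnostic procedures, therapeutic
procedures, sensory perception and skin integrity -- are each rated on an
assistance level 1-4, giving a total of 8-32 that classifies the patient's
care-dependence level.

Two cutpoint schemes circulate for the level classification and both are
supported: ``text_bands`` (low 8-14, average 15-23, high 24-32; the default,
and the one the ICC matrix is defined on) and ``table8_bands`` (low 8-16,
average 17-25, high >=26).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .errors import RangeError, ValidationError

__all__ = [
    "CUTPOINT_SCHEMES",
    "DIMENSIONS",
    "LEVEL_LABELS",
    "MicdAssessment",
    "MicdResult",
    "classify_dependence",
    "score_micd",
]

DIMENSIONS = (
    "nutrition_hydration",
    "elimination",
    "hygiene_comfort",
    "mobilization",
    "diagnostic_procedures",
    "therapeutic_procedures",
    "sensory_perception",
    "skin_integrity",
)

LEVEL_LABELS = ("low", "average", "high")

#: (upper bound of low, upper bound of average); high is the remainder to 32
CUTPOINT_SCHEMES: dict[str, tuple[int, int]] = {
    "text_bands": (14, 23),
    "table8_bands": (16, 25),
}

CONTEXTS = ("admission", "setting_transfer")


@dataclass(frozen=True)
class MicdAssessment:
    """One eight-dimension rubric assessment at admission or transfer."""

    nutrition_hydration: int
    elimination: int
    hygiene_comfort: int
    mobilization: int
    diagnostic_procedures: int
    therapeutic_procedures: int
    sensory_perception: int
    skin_integrity: int
    assessed_at: date | None = None
    context: str = "admission"

    def levels(self) -> tuple[int, ...]:
        return tuple(getattr(self, d) for d in DIMENSIONS)

    def validate(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level is None:
                raise ValidationError(f"mICD dimension '{dim}' is missing")
            if not (isinstance(level, int) or float(level).is_integer()):
                raise ValidationError(f"mICD dimension '{dim}' must be an integer")
            if not 1 <= int(level) <= 4:
                raise ValidationError(
                    f"mICD dimension '{dim}'={level!r} outside levels 1..4"
                )
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"context must be one of {CONTEXTS}, got {self.context!r}"
            )


@dataclass(frozen=True)
class MicdResult:
    total: int
    level: str


def classify_dependence(total: int, scheme: str = "text_bands") -> str:
    """Classify an mICD total into low / average / high dependence."""
    total = int(total)
    if not 8 <= total <= 32:
        raise RangeError(f"mICD total must be in 8..32, got {total}")
    try:
        low_max, avg_max = CUTPOINT_SCHEMES[scheme]
    except KeyError:
        raise ValidationError(
            f"unknown cutpoint scheme {scheme!r}; choose from {sorted(CUTPOINT_SCHEMES)}"
        ) from None
    if total <= low_max:
        return "low"
    if total <= avg_max:
        return "average"
    return "high"


def score_micd(assessment: MicdAssessment, scheme: str = "text_bands") -> MicdResult:
    """Sum the eight dimension levels and classify the dependence level."""
    assessment.validate()
    total = sum(int(v) for v in assessment.levels())
    return MicdResult(total=total, level=classify_dependence(total, scheme))
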