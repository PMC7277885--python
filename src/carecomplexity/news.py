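"""National Early Warning Score (NEWS) computation.

The NEWS aggregates six physiological parameters -- respiration rate,
oxygen saturation, temperature, systolic blood pressure, heart rate and
level of consciousness (AVPU) -- each mapped to a 0-3 sub-score through a
band table, plus a 2-point add-on for patients on supplemental oxygen.
The total (0-20) is banded into a clinical-instability level: *stable*
(0-4), *unstable* (5-6) or *critical* (>=7).

The shipped default band table is the Royal College of Physicians NEWS
(2012) form, loaded from ``data/news_bands.default.yaml``; alternative
local variants can be supplied as YAML with the same structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .errors import MissingDataError, RangeError, ValidationError

__all__ = [
    "AVPU_LABELS",
    "BAND_LABELS",
    "BandTable",
    "NewsResult",
    "VitalSigns",
    "classify_instability",
    "default_band_table",
    "load_band_table",
    "score_news",
]

AVPU_LABELS = ("Alert", "Verbal", "Pain", "Unresponsive")
BAND_LABELS = ("stable", "unstable", "critical")

#: physiologic sanity bounds (inclusive) used by input validation
DEFAULT_SANITY_BOUNDS: dict[str, tuple[float, float]] = {
    "respiration_rate": (0, 80),
    "spo2": (50, 100),
    "temperature": (25.0, 45.0),
    "systolic_bp": (30, 300),
    "heart_rate": (0, 300),
}

#: fields scored through interval lookup, in canonical component order
NUMERIC_COMPONENTS = (
    "respiration_rate",
    "spo2",
    "temperature",
    "systolic_bp",
    "heart_rate",
)


@dataclass(frozen=True)
class VitalSigns:
    """One timestamped set of the six NEWS parameters plus the oxygen flag."""

    respiration_rate: int
    spo2: int
    supplemental_oxygen: bool
    temperature: float
    systolic_bp: int
    heart_rate: int
    avpu: str
    observed_at: date | datetime | None = None

    def validate(self, bounds: Mapping[str, tuple[float, float]] | None = None) -> None:
        """Check sanity bounds and the AVPU label; raise naming the field."""
        bounds = dict(DEFAULT_SANITY_BOUNDS, **(bounds or {}))
        for name in NUMERIC_COMPONENTS:
            value = getattr(self, name)
            if value is None:
                raise MissingDataError(f"vital sign '{name}' is missing")
            if not math.isfinite(float(value)):
                raise ValidationError(f"vital sign '{name}' is not finite: {value!r}")
            lo, hi = bounds[name]
            if not lo <= float(value) <= hi:
                raise ValidationError(
                    f"vital sign '{name}'={value!r} outside sanity bounds [{lo}, {hi}]"
                )
        if self.avpu not in AVPU_LABELS:
            raise ValidationError(
                f"avpu must be one of {AVPU_LABELS}, got {self.avpu!r}"
            )
        if not isinstance(self.supplemental_oxygen, (bool,)):
            raise ValidationError("supplemental_oxygen must be a boolean")


@dataclass(frozen=True)
class NewsResult:
    component_scores: dict[str, int]
    total: int
    band: str


@dataclass(frozen=True)
class Interval:
    """Closed interval [min, max] with a sub-score; open ends are None."""

    min: float | None
    max: float | None
    score: int

    def contains(self, value: float) -> bool:
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value > self.max:
            return False
        return True


@dataclass(frozen=True)
class BandTable:
    """Per-parameter scoring intervals plus total-score band cutpoints.

    ``parameters`` maps each numeric component to an ordered list of closed
    intervals.  ``avpu_scores`` maps consciousness labels to sub-scores and
    ``oxygen_score`` is the add-on applied when supplemental oxygen is on.
    ``band_cutpoints`` are the inclusive upper bounds of the stable and
    unstable bands.
    """

    parameters: dict[str, tuple[Interval, ...]]
    avpu_scores: dict[str, int]
    oxygen_score: int = 2
    band_cutpoints: tuple[int, int] = (4, 6)
    sanity_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SANITY_BOUNDS)
    )

    def __post_init__(self) -> None:
        missing = set(NUMERIC_COMPONENTS) - set(self.parameters)
        if missing:
            raise ValidationError(f"band table missing parameters: {sorted(missing)}")
        lo_cut, hi_cut = self.band_cutpoints
        if not lo_cut < hi_cut:
            raise ValidationError("band cutpoints must be strictly increasing")
        for name, intervals in self.parameters.items():
            self._check_cover(name, intervals)

    def _check_cover(self, name: str, intervals: Sequence[Interval]) -> None:
        """Intervals must be disjoint and jointly cover the sanity range."""
        lo, hi = self.sanity_bounds[name]
        step = 0.1 if name == "temperature" else 1
        ordered = sorted(intervals, key=lambda iv: -math.inf if iv.min is None else iv.min)
        cursor = lo
        for iv in ordered:
            left = lo if iv.min is None else max(iv.min, lo)
            if left > cursor + step / 2:
                raise ValidationError(
                    f"band table gap in '{name}' before {left}"
                )
            if left < cursor - step / 2:
                raise ValidationError(f"band table overlap in '{name}' at {left}")
            cursor = hi + step if iv.max is None else iv.max + step
        if cursor < hi + step / 2:
            raise ValidationError(f"band table for '{name}' does not reach {hi}")

    def lookup(self, name: str, value: float) -> int:
        # printed endpoints are closed; compare after rounding to the form's
        # precision (0.1 degC for temperature, whole units otherwise)
        rounded = round(value, 1) if name == "temperature" else round(value)
        for iv in self.parameters[name]:
            if iv.contains(rounded):
                return iv.score
        raise RangeError(f"value {value!r} not covered by band table for '{name}'")


def _parse_intervals(raw: Sequence[Mapping]) -> tuple[Interval, ...]:
    return tuple(
        Interval(
            min=None if r.get("min") is None else float(r["min"]),
            max=None if r.get("max") is None else float(r["max"]),
            score=int(r["score"]),
        )
        for r in raw
    )


def load_band_table(source) -> BandTable:
    """Load a :class:`BandTable` from a YAML mapping, path or file object."""
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    kwargs: dict = {}
    if "sanity_bounds" in doc:
        kwargs["sanity_bounds"] = {
            k: (float(v[0]), float(v[1])) for k, v in doc["sanity_bounds"].items()
        }
    return BandTable(
        parameters={
            name: _parse_intervals(doc["parameters"][name])
            for name in doc["parameters"]
        },
        avpu_scores={k: int(v) for k, v in doc["avpu"].items()},
        oxygen_score=int(doc.get("oxygen_score", 2)),
        band_cutpoints=tuple(int(c) for c in doc.get("band_cutpoints", (4, 6))),
        **kwargs,
    )


def default_band_table() -> BandTable:
    """The RCP NEWS (2012) band table shipped with the package."""
    ref = resources.files("carecomplexity.data").joinpath("news_bands.default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_band_table(fh)


def classify_instability(total: int, cutpoints: tuple[int, int] = (4, 6)) -> str:
    """Band a NEWS total: 0-4 stable, 5-6 unstable, >=7 critical."""
    total = int(total)
    if not 0 <= total <= 20:
        raise RangeError(f"NEWS total must be in 0..20, got {total}")
    lo, hi = cutpoints
    if total <= lo:
        return "stable"
    if total <= hi:
        return "unstable"
    return "critical"


def score_news(vitals: VitalSigns, bands: BandTable | None = None) -> NewsResult:
    """Score one set of vital signs against a band table.

    Returns the seven component sub-scores (six physiological lookups plus
    the supplemental-oxygen add-on), their sum, and the instability band.
    """
    if bands is None:
        bands = default_band_table()
    vitals.validate(bands.sanity_bounds)
    components: dict[str, int] = {}
    for name in NUMERIC_COMPONENTS:
        components[name] = bands.lookup(name, float(getattr(vitals, name)))
    components["avpu"] = bands.avpu_scores[vitals.avpu]
    components["supplemental_oxygen"] = (
        bands.oxygen_score if vitals.supplemental_oxygen else 0
    )
    total = sum(components.values())
    return NewsResult(
        component_scores=components,
        total=total,
        band=classify_instability(total, bands.band_cutpoints),
    )
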