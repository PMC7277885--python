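"""Index of Caring Complexity (ICC): NEWS band x mICD level matrix.

The ICC integrates clinical instability (the NEWS band) with care
dependence (the mICD level) through a 3x3 categorical matrix into a
Low / Medium / High care-complexity class.  The matrix is data, not code:
hospitals adapting the model can supply their own YAML, provided it stays
monotone (higher instability or dependence never lowers the complexity).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .errors import ValidationError
from .micd import LEVEL_LABELS
from .news import BAND_LABELS

__all__ = [
    "ICC_LABELS",
    "IccMatrix",
    "classify_icc",
    "default_icc_matrix",
    "load_icc_matrix",
]

ICC_LABELS = ("Low", "Medium", "High")
_ICC_RANK = {label: i for i, label in enumerate(ICC_LABELS)}


@dataclass(frozen=True)
class IccMatrix:
    """Total 3x3 mapping (band, level) -> ICC class, monotone in both axes."""

    cells: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for band in BAND_LABELS:
            for level in LEVEL_LABELS:
                value = self.cells.get((band, level))
                if value is None:
                    raise ValidationError(f"ICC matrix missing cell ({band}, {level})")
                if value not in ICC_LABELS:
                    raise ValidationError(
                        f"ICC matrix cell ({band}, {level}) has unknown class {value!r}"
                    )
        for i, band in enumerate(BAND_LABELS):
            for j, level in enumerate(LEVEL_LABELS):
                here = _ICC_RANK[self.cells[band, level]]
                if i + 1 < len(BAND_LABELS):
                    worse = _ICC_RANK[self.cells[BAND_LABELS[i + 1], level]]
                    if worse < here:
                        raise ValidationError(
                            "ICC matrix not monotone along the instability axis"
                        )
                if j + 1 < len(LEVEL_LABELS):
                    worse = _ICC_RANK[self.cells[band, LEVEL_LABELS[j + 1]]]
                    if worse < here:
                        raise ValidationError(
                            "ICC matrix not monotone along the dependence axis"
                        )

    def cell(self, band: str, level: str) -> str:
        return classify_icc(band, level, self)


def classify_icc(band: str, level: str, matrix: "IccMatrix | None" = None) -> str:
    """Look up the ICC class for a NEWS band and an mICD level."""
    if matrix is None:
        matrix = default_icc_matrix()
    if band not in BAND_LABELS:
        raise ValidationError(f"unknown NEWS band {band!r}; expected {BAND_LABELS}")
    if level not in LEVEL_LABELS:
        raise ValidationError(f"unknown mICD level {level!r}; expected {LEVEL_LABELS}")
    return matrix.cells[band, level]


def load_icc_matrix(source) -> IccMatrix:
    """Load an :class:`IccMatrix` from a YAML mapping, path or file object."""
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    cells = {
        (band, level): str(doc[band][level])
        for band in doc
        for level in doc[band]
    }
    return IccMatrix(cells=cells)


def default_icc_matrix() -> IccMatrix:
    """The shipped default matrix.

    stable: (Low, Medium, High); unstable: (Medium, Medium, High);
    critical: (High, High, High) -- columns ordered low/average/high.
    """
    ref = resources.files("carecomplexity.data").joinpath("icc_matrix.default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_icc_matrix(fh)
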