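"""Colonization indices and Trouvelot class assignment.

Two per-image indices quantify root colonization intensity:

* the thresholding index ``t = 100 * mycorrhized_area / total_root_area``,
  from brightness thresholding of the grayscale micrograph;
* the machine-learning index
  ``ml = 100 * colonized_area / (colonized_area + non_colonized_area)``,
  from per-pixel classification.

Both are area ratios in [0, 100] and are scale-free: rescaling both areas
by the same factor leaves them unchanged.  The Trouvelot visual scoring
assigns each root segment to one of six colonization-intensity classes,
from class 1 (no infection) through class 6 (more than 90 % colonized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["ColonizationMeasure", "t_index", "ml_index", "trouvelot_class"]

#: Default boundary between "few traces" (class 2) and "< 10 %" (class 3),
#: in percent.  The visual criterion is qualitative, so this is configurable.
DEFAULT_TRACE_CUTOFF = 1.0


@dataclass(frozen=True)
class ColonizationMeasure:
    """Areas, index, and class assignment for one image.

    ``reference_area`` is the total root area for the t-index and the
    colonized + non-colonized area for the ml-index.
    """

    image_id: str
    colonized_area: int
    reference_area: int
    index_value: float
    method: str  # "threshold" or "ml"
    trouvelot_class: int
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.colonized_area <= self.reference_area or
                self.reference_area == 0 and self.colonized_area == 0):
            raise ValidationError(
                f"colonized_area {self.colonized_area} outside "
                f"[0, reference_area={self.reference_area}]"
            )
        if self.method not in ("threshold", "ml"):
            raise ValidationError(f"unknown method {self.method!r}")
        if not 1 <= self.trouvelot_class <= 6:
            raise ValidationError("trouvelot_class must be in 1..6")


def t_index(mycorrhized_area: float, total_area: float) -> float:
    """Thresholding index: 100 * mycorrhized_area / total_area.

    A zero total area yields 0.0 (callers should flag the record "empty").
    """
    if mycorrhized_area < 0 or total_area < 0:
        raise ValidationError("areas must be non-negative")
    if mycorrhized_area > total_area:
        raise ValidationError(
            f"mycorrhized area {mycorrhized_area} exceeds total area {total_area}"
        )
    if total_area == 0:
        return 0.0
    return 100.0 * mycorrhized_area / total_area


def ml_index(colonized_area: float, non_colonized_area: float) -> float:
    """Machine-learning index: 100 * c / (c + n).

    Identical to ``t_index(c, c + n)``; both areas zero yields 0.0.
    """
    if colonized_area < 0 or non_colonized_area < 0:
        raise ValidationError("areas must be non-negative")
    denom = colonized_area + non_colonized_area
    if denom == 0:
        return 0.0
    return 100.0 * colonized_area / denom


def trouvelot_class(percentage: float, trace_cutoff: float = DEFAULT_TRACE_CUTOFF) -> int:
    """Assign a colonization percentage to one of the six visual classes.

    Classes follow the standard visual criteria — 1: no infection; 2: few
    traces; 3: < 10 %; 4: 11–50 %; 5: 51–90 %; 6: > 90 % — made total over
    [0, 100] by half-open intervals with boundaries at ``trace_cutoff``,
    10, 50 and 90: 0 -> 1; (0, trace_cutoff] -> 2; (trace_cutoff, 10] -> 3;
    (10, 50] -> 4; (50, 90] -> 5; (90, 100] -> 6.
    """
    if not (0.0 <= percentage <= 100.0):
        raise ValidationError(f"percentage {percentage} outside [0, 100]")
    if not (0.0 < trace_cutoff <= 10.0):
        raise ValidationError("trace_cutoff must lie in (0, 10]")
    if percentage == 0:
        return 1
    if percentage <= trace_cutoff:
        return 2
    if percentage <= 10:
        return 3
    if percentage <= 50:
        return 4
    if percentage <= 90:
        return 5
    return 6
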