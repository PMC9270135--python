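"""Clinical severity scoring for melasma.

Implements the MASI (Melasma Area and Severity Index) composite score, the
MASI decline (reduction) rate, the four-grade treatment-outcome classifier,
and the five-parameter ordinal grading used for reflectance confocal
microscopy (RCM) readings.

MASI combines, per facial region r, an area grade A_r (0-6) with darkness
D_r and homogeneity H_r grades (0-4 each):

    M = 0.3*A_F*(D_F+H_F) + 0.3*A_MR*(D_MR+H_MR)
      + 0.3*A_ML*(D_ML+H_ML) + 0.1*A_C*(D_C+H_C)

giving a score in [0, 48]. Treatment response is the relative drop in MASI
from baseline Vb to post-treatment Va, classified into four ordered grades
(invalid / get better / effective / basically healed).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Union


class Region(enum.Enum):
    """Facial region of a MASI assessment."""

    FOREHEAD = "F"
    RIGHT_MALAR = "MR"
    LEFT_MALAR = "ML"
    CHIN = "C"


#: Regional weights of the MASI sum. The chin (mandible) carries 0.1, the
#: forehead and each malar region 0.3.
MASI_WEIGHTS: dict[Region, float] = {
    Region.FOREHEAD: 0.3,
    Region.RIGHT_MALAR: 0.3,
    Region.LEFT_MALAR: 0.3,
    Region.CHIN: 0.1,
}


@dataclass(frozen=True)
class RegionAssessment:
    """MASI components for one facial region.

    Parameters
    ----------
    region
        One of the four MASI facial regions.
    darkness
        Pigment darkness grade D, integer 0-4.
    homogeneity
        Homogeneity (consistency of color distribution) grade H, integer 0-4.
    area
        Involved-area grade A, integer 0-6.
    """

    region: Region
    darkness: int
    homogeneity: int
    area: int

    def __post_init__(self) -> None:
        if not isinstance(self.region, Region):
            raise ValueError(f"region must be a Region, got {self.region!r}")
        for name, value, hi in (
            ("darkness", self.darkness, 4),
            ("homogeneity", self.homogeneity, 4),
            ("area", self.area, 6),
        ):
            if not (isinstance(value, int) and 0 <= value <= hi):
                raise ValueError(f"{name} must be an integer in [0, {hi}], got {value!r}")


@dataclass(frozen=True)
class MASIPair:
    """MASI score before (``value_before``) and after (``value_after``) treatment."""

    value_before: float
    value_after: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value_before) and self.value_before >= 0):
            raise ValueError(f"value_before must be finite and >= 0, got {self.value_before!r}")
        if not (math.isfinite(self.value_after) and self.value_after >= 0):
            raise ValueError(f"value_after must be finite and >= 0, got {self.value_after!r}")


class OutcomeGrade(enum.IntEnum):
    """Ordered treatment-outcome grade; the integer code preserves the order."""

    INVALID = 0
    GET_BETTER = 1
    EFFECTIVE = 2
    BASICALLY_HEALED = 3


class RCMParameter(enum.Enum):
    """The five ordinal RCM severity parameters."""

    EPIDERMAL_PIGMENTATION = "pigment"
    DENDRITIC_CELLS = "dendritic"
    MELANOPHAGES = "melanophage"
    SOLAR_ELASTOSIS = "elastosis"
    VASCULARITY = "vascularity"


class Severity(enum.IntEnum):
    """Qualitative severity scale for elastosis and vascularity."""

    NORMAL = 1
    MILD = 2
    MODERATE = 3
    SERIOUS = 4


@dataclass(frozen=True)
class RCMAssessment:
    """One patient's five RCM scores, each an ordinal in {1, 2, 3, 4}."""

    epidermal_pigmentation_score: int
    dendritic_cell_score: int
    melanophage_score: int
    solar_elastosis_score: int
    vascularity_score: int

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value not in (1, 2, 3, 4):
                raise ValueError(f"{name} must be in {{1,2,3,4}}, got {value!r}")

    def as_dict(self) -> dict[str, int]:
        return {
            "epidermal_pigmentation_score": self.epidermal_pigmentation_score,
            "dendritic_cell_score": self.dendritic_cell_score,
            "melanophage_score": self.melanophage_score,
            "solar_elastosis_score": self.solar_elastosis_score,
            "vascularity_score": self.vascularity_score,
        }

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (
            self.epidermal_pigmentation_score,
            self.dendritic_cell_score,
            self.melanophage_score,
            self.solar_elastosis_score,
            self.vascularity_score,
        )


def masi_score(regions: Iterable[RegionAssessment]) -> float:
    """Compute the MASI score from exactly one assessment per facial region.

    Returns the weighted sum ``sum_r w_r * A_r * (D_r + H_r)`` with weights
    0.3 (forehead, each malar) and 0.1 (chin); the result lies in [0, 48].

    Raises
    ------
    ValueError
        If a region is missing or assessed more than once.
    """
    by_region: dict[Region, RegionAssessment] = {}
    for assessment in regions:
        if assessment.region in by_region:
            raise ValueError(f"duplicate assessment for region {assessment.region.value}")
        by_region[assessment.region] = assessment
    missing = [r.value for r in Region if r not in by_region]
    if missing:
        raise ValueError(f"missing assessment for region(s): {', '.join(missing)}")
    return sum(
        MASI_WEIGHTS[r] * a.area * (a.darkness + a.homogeneity)
        for r, a in by_region.items()
    )


def masi_decline_rate(
    pair: MASIPair, denominator: Literal["before", "after"] = "before"
) -> float:
    """Relative MASI drop (Vb - Va) / Vb, as a fraction.

    Equals 1 for complete clearance (Va = 0) and is negative when the score
    worsened. ``denominator="after"`` divides by the post-treatment score
    instead; with the default baseline denominator the rate is bounded above
    by 1, which is what the grade bands assume.

    Raises
    ------
    ValueError
        If the chosen denominator is zero (undefined baseline).
    """
    vb, va = pair.value_before, pair.value_after
    denom = vb if denominator == "before" else va
    if denom == 0:
        raise ValueError("decline rate undefined: denominator MASI value is 0")
    return (vb - va) / denom


# Grade band lower edges on the decline-rate fraction scale; half-open
# intervals [lo, next_lo) so every finite rate maps to exactly one grade.
GRADE_THRESHOLDS: tuple[float, float, float] = (0.10, 0.50, 0.90)


def grade_outcome(decline_rate: float) -> OutcomeGrade:
    """Classify a MASI decline rate (fraction) into the four outcome grades.

    >= 0.90 is basically healed, [0.50, 0.90) effective, [0.10, 0.50)
    get better, and below 0.10 invalid (no response).
    """
    if not math.isfinite(decline_rate):
        raise ValueError(f"decline_rate must be finite, got {decline_rate!r}")
    lo_better, lo_effective, lo_healed = GRADE_THRESHOLDS
    if decline_rate >= lo_healed:
        return OutcomeGrade.BASICALLY_HEALED
    if decline_rate >= lo_effective:
        return OutcomeGrade.EFFECTIVE
    if decline_rate >= lo_better:
        return OutcomeGrade.GET_BETTER
    return OutcomeGrade.INVALID


def rcm_grade(
    parameter: RCMParameter, measurement: Union[float, int, Severity, str]
) -> int:
    """Map a raw RCM measurement to its ordinal score in {1, 2, 3, 4}.

    The measurement type depends on the parameter: epidermal pigmentation is
    a density fraction in [0, 1] (quartile bands, half-open above the lower
    edge); dendritic cells and melanophages are non-negative counts per
    field (0 / up-to-5 / up-to-15-or-10 / above); solar elastosis and
    vascularity are qualitative severities (normal/mild/moderate/serious).
    """
    if parameter is RCMParameter.EPIDERMAL_PIGMENTATION:
        frac = float(measurement)
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"pigmentation fraction must be in [0,1], got {frac!r}")
        if frac <= 0.25:
            return 1
        if frac <= 0.50:
            return 2
        if frac <= 0.75:
            return 3
        return 4
    if parameter in (RCMParameter.DENDRITIC_CELLS, RCMParameter.MELANOPHAGES):
        count = float(measurement)
        if not (math.isfinite(count) and count >= 0):
            raise ValueError(f"cell count must be >= 0, got {measurement!r}")
        if count == 0:
            return 1
        if count <= 5:
            return 2
        band3_hi = 15 if parameter is RCMParameter.DENDRITIC_CELLS else 10
        if count <= band3_hi:
            return 3
        return 4
    # qualitative severity scale
    if isinstance(measurement, str):
        try:
            measurement = Severity[measurement.upper()]
        except KeyError:
            raise ValueError(f"unknown severity {measurement!r}") from None
    if not isinstance(measurement, Severity):
        raise ValueError(
            f"{parameter.value} expects a Severity or its name, got {measurement!r}"
        )
    return int(measurement)


#: Continuous target encoding of each grade: the midpoint of its decline-rate
#: band. Strictly increasing in grade order; used as the network's regression
#: target for graded patients.
GRADE_TARGETS: dict[OutcomeGrade, float] = {
    OutcomeGrade.INVALID: 0.05,
    OutcomeGrade.GET_BETTER: 0.30,
    OutcomeGrade.EFFECTIVE: 0.70,
    OutcomeGrade.BASICALLY_HEALED: 0.95,
}


def grade_to_target(grade: OutcomeGrade) -> float:
    """Continuous treatment-effect target in [0, 1] encoding an outcome grade."""
    if not isinstance(grade, OutcomeGrade):
        raise ValueError(f"grade must be an OutcomeGrade, got {grade!r}")
    return GRADE_TARGETS[grade]
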