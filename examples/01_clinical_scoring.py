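"""Score a patient's MASI, grade the treatment response, and grade raw RCM readings.

Builds one before/after pair of MASI region assessments, computes the
composite score and its decline rate, classifies the outcome, and maps a
set of raw reflectance-confocal-microscopy measurements onto the 1-4
ordinal severity scale.
"""

from melasma_gabp import (
    MASIPair,
    RCMParameter,
    Region,
    RegionAssessment,
    grade_outcome,
    masi_decline_rate,
    masi_score,
    rcm_grade,
)

before = [
    RegionAssessment(Region.FOREHEAD, darkness=3, homogeneity=2, area=4),
    RegionAssessment(Region.RIGHT_MALAR, darkness=4, homogeneity=3, area=5),
    RegionAssessment(Region.LEFT_MALAR, darkness=4, homogeneity=2, area=5),
    RegionAssessment(Region.CHIN, darkness=2, homogeneity=1, area=2),
]
after = [
    RegionAssessment(Region.FOREHEAD, darkness=1, homogeneity=1, area=2),
    RegionAssessment(Region.RIGHT_MALAR, darkness=1, homogeneity=1, area=2),
    RegionAssessment(Region.LEFT_MALAR, darkness=1, homogeneity=0, area=2),
    RegionAssessment(Region.CHIN, darkness=0, homogeneity=0, area=1),
]

masi_before = masi_score(before)
masi_after = masi_score(after)
rate = masi_decline_rate(MASIPair(masi_before, masi_after))
grade = grade_outcome(rate)

print(f"MASI before treatment: {masi_before:.1f}   (scale 0-48)")
print(f"MASI after treatment:  {masi_after:.1f}")
print(f"Decline rate:          {rate:.1%}  -> grade: {grade.name.lower()}")
# The decline rate is the fractional drop from baseline; 50-89% counts as
# an effective response, >= 90% as basically healed.

print("\nRCM ordinal grading of raw measurements:")
readings = [
    (RCMParameter.EPIDERMAL_PIGMENTATION, 0.42),  # pigmented-field fraction
    (RCMParameter.DENDRITIC_CELLS, 7),            # cells per field
    (RCMParameter.MELANOPHAGES, 2),               # cells per field
    (RCMParameter.SOLAR_ELASTOSIS, "moderate"),
    (RCMParameter.VASCULARITY, "mild"),
]
for parameter, raw in readings:
    print(f"  {parameter.value:12s} {raw!s:>8} -> score {rcm_grade(parameter, raw)}")
# Each score is the 1-4 severity column of the RCM grading scheme; these
# five scores form a patient's feature vector for the network.
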