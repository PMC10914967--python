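"""Bundled example data.

A published patient-demand survey of 14 general-practice teaching-clinic
service items (101 valid questionnaires): per item, the counts of
respondents classified into each Kano category.  This is the worked example
used throughout the documentation and tests.
"""

from __future__ import annotations

from .classification import ItemFrequencyTable
from .core import KanoCategory

# item_id -> (label, (A, I, M, O, R, Q) counts)
_TEACHING_CLINIC = {
    "1": ("A comfortable clinic environment", (31, 17, 30, 23, 0, 0)),
    "2": ("Various convenient ways of registration", (32, 10, 34, 25, 0, 0)),
    "3": ("Advance notice of the specific process and time", (35, 16, 26, 24, 0, 0)),
    "4": ("Good service attitude", (32, 9, 27, 33, 0, 0)),
    "5": (
        "The resident physician in training leads the treatment process",
        (39, 44, 5, 6, 7, 0),
    ),
    "6": (
        "The superior physician provides supplementary consultation",
        (15, 1, 38, 47, 0, 0),
    ),
    "7": ("Participate in teacher-student interaction", (37, 44, 3, 10, 7, 0)),
    "8": (
        "Explain the condition and test results in detail and agree on the "
        "treatment plan together",
        (30, 29, 21, 21, 0, 0),
    ),
    "9": ("Sufficient consultation time (30 min)", (34, 30, 15, 22, 0, 0)),
    "10": ("Health guidance on lifestyle and home care", (44, 12, 12, 33, 0, 0)),
    "11": ("Skilled in the inspection and operation", (9, 3, 54, 35, 0, 0)),
    "12": ("Fixed medical team and consistent treatment", (14, 28, 24, 35, 0, 0)),
    "13": ("Reasonable cost for examinations and treatments", (5, 5, 38, 53, 0, 0)),
    "14": ("Consistent efficacy meets expectations", (2, 2, 31, 66, 0, 0)),
}

_ORDER = (
    KanoCategory.A,
    KanoCategory.I,
    KanoCategory.M,
    KanoCategory.O,
    KanoCategory.R,
    KanoCategory.Q,
)


def teaching_clinic_frequencies() -> list[ItemFrequencyTable]:
    """The 14-item teaching-clinic frequency table (N = 101 per item)."""
    return [
        ItemFrequencyTable(
            item_id=item_id,
            counts=dict(zip(_ORDER, counts)),
            label=label,
        )
        for item_id, (label, counts) in _TEACHING_CLINIC.items()
    ]
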