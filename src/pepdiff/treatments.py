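"""Clinical conditions, search channels, and the 26-level treatment encoding.

Each plasma sample set belongs to one of 13 disease/control conditions and every
MS/MS search is run in two channels: plain fully-tryptic peptides (``TRYP``) and
tryptic phosphopeptides with Ser/Thr/Tyr phosphorylation allowed (``STYP``).
A *treatment* is one condition x channel cell; the integer treatment ids 1-26
interleave the two channels in a fixed condition order (odd = TRYP, even = STYP).
"""

from __future__ import annotations

from typing import Tuple

#: Conditions in treatment-id order: condition i (0-based) owns ids 2i+1 (TRYP)
#: and 2i+2 (STYP).
CONDITIONS: tuple[str, ...] = (
    "alzheimer_normal",
    "alzheimer_dementia",
    "breast_cancer",
    "cancer_control",
    "ovarian_cancer",
    "ice_cold",
    "heart_attack_arterial",
    "heart_attack_normal_control",
    "heart_attack_venous",
    "multiple_sclerosis_normal_control",
    "multiple_sclerosis",
    "sepsis",
    "sepsis_normal_control",
)

SEARCH_TYPES: tuple[str, ...] = ("TRYP", "STYP")

#: Human-readable labels for reports.
CONDITION_LABELS = {
    "alzheimer_normal": "Alzheimer normal",
    "alzheimer_dementia": "Alzheimer's dementia",
    "breast_cancer": "Cancer breast",
    "cancer_control": "Cancer control",
    "ovarian_cancer": "Cancer ovarian",
    "ice_cold": "Ice cold",
    "heart_attack_arterial": "Heart attack arterial",
    "heart_attack_normal_control": "Heart attack normal control",
    "heart_attack_venous": "Heart attack",
    "multiple_sclerosis_normal_control": "Multiple sclerosis normal control",
    "multiple_sclerosis": "Multiple sclerosis",
    "sepsis": "Sepsis",
    "sepsis_normal_control": "Sepsis normal control",
}

_CONDITION_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

N_TREATMENTS = 2 * len(CONDITIONS)


class UnknownTreatmentError(KeyError):
    """Raised for a condition/search-type/treatment-id outside the enumeration."""


def map_treatment(condition: str, search_type: str) -> int:
    """Return the integer treatment id (1-26) for a condition x channel cell.

    >>> map_treatment("breast_cancer", "TRYP")
    5
    >>> map_treatment("ovarian_cancer", "STYP")
    10
    """
    try:
        base = 2 * _CONDITION_INDEX[condition] + 1
    except KeyError:
        raise UnknownTreatmentError(f"unknown condition: {condition!r}") from None
    if search_type not in SEARCH_TYPES:
        raise UnknownTreatmentError(f"unknown search_type: {search_type!r}")
    return base + (search_type == "STYP")


def unmap_treatment(treatment_id: int) -> Tuple[str, str]:
    """Inverse of :func:`map_treatment`."""
    if not 1 <= int(treatment_id) <= N_TREATMENTS:
        raise UnknownTreatmentError(f"treatment id out of range: {treatment_id}")
    tid = int(treatment_id) - 1
    return CONDITIONS[tid // 2], SEARCH_TYPES[tid % 2]


def treatment_label(treatment_id: int) -> str:
    cond, st = unmap_treatment(treatment_id)
    label = CONDITION_LABELS[cond]
    return label if st == "TRYP" else f"{label} STYP"
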