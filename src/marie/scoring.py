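"""Scoring of the twelve drug value elements.

Four *base* elements (efficacy, safety, scientific novelty, clinical
positioning) are always assessed and sum to 25–50 base points; eight
*additional* elements contribute 0–50 premium points.  Each element has a
small fixed vocabulary of criterion levels; points are a pure function of
(element, level).

Assessment documents are flat mappings ``element name -> level token`` (plus
``drug_id``).  Additional elements may be omitted, which scores them at
their zero level; base elements are mandatory.  The "others" element, being
a catch-all with no objective criterion, requires a free-text justification
whenever it is scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

__all__ = [
    "BaseElementLevel",
    "AdditionalElementLevel",
    "ValueAssessment",
    "AssessmentError",
    "BASE_ELEMENTS",
    "ADDITIONAL_ELEMENTS",
    "BASE_CRITERIA",
    "ADDITIONAL_CRITERIA",
    "score_base",
    "score_additional",
    "validate_assessment",
]

# element -> level token -> (points, human-language criterion)
BASE_CRITERIA: dict[str, dict[str, tuple[int, str]]] = {
    "efficacy": {
        "superiority": (20, "Superiority over active comparator"),
        "non_inferiority": (15, "Non-inferiority over active comparator, "
                                "superiority over placebo, or superiority as "
                                "add-on therapy over standard of care alone"),
        "single_arm": (10, "Evaluated in a single-armed trial"),
    },
    "safety": {
        "acceptable_with_surveillance": (10, "Acceptable; information to be "
                                             "gathered in post-marketing surveillance"),
        "acceptable_with_warnings": (5, "Acceptable, but issues for warnings or "
                                        "contraindications discussed at approval"),
    },
    "scientific_novelty": {
        "novel_mechanism": (10, "Efficacy shown or expected, with a novel "
                                "mechanism of action"),
        "efficacy_shown": (5, "Efficacy shown or expected to be shown"),
    },
    "clinical_positioning": {
        "new_option": (10, "New or first treatment option"),
        "one_of_several": (5, "One of several treatment options"),
    },
}

ADDITIONAL_CRITERIA: dict[str, dict[str, tuple[int, str]]] = {
    "unmet_needs": {
        "low_satisfaction_low_contribution": (5, "Treatment satisfaction < 50% "
                                                 "and drug contribution < 50%"),
        "low_satisfaction_high_contribution": (3, "Treatment satisfaction < 50% "
                                                  "and drug contribution > 50%"),
        "high_satisfaction_low_contribution": (3, "Treatment satisfaction > 50% "
                                                  "and drug contribution < 50%"),
        "high_satisfaction_high_contribution": (1, "Treatment satisfaction > 50% "
                                                   "and drug contribution > 50%"),
        "not_applicable": (0, "No unmet-need premium claimed"),
    },
    "qol": {
        "improved": (5, "Improvement from baseline or against placebo or an "
                        "active comparator observed"),
        "not_observed": (0, "Improvement not observed or data not available"),
    },
    "true_endpoints": {
        "improved": (5, "Improvement observed"),
        "not_observed": (0, "Improvement not observed or data not available"),
    },
    "productivity_loss": {
        "reports_available": (5, "Productivity-loss reports available for the "
                                 "indicated disease"),
        "no_reports": (0, "No productivity-loss reports for the indicated disease"),
    },
    "convenience": {
        "improved": (5, "e.g. self-administration possible, administration "
                        "interval extended, or frequency reduced"),
        "none": (0, "No convenience improvement"),
    },
    "diagnosis": {
        "improved": (5, "Improvement observed"),
        "not_observed": (0, "Improvement not observed or data not available"),
    },
    "pediatric_use": {
        "approved": (10, "Approved for use in children"),
        "not_approved": (0, "Not approved for use in children"),
    },
    "others": {
        "applicable": (10, "Other documented value (justification required)"),
        "not_applicable": (0, "Not applicable"),
    },
}

BASE_ELEMENTS: tuple[str, ...] = tuple(BASE_CRITERIA)
ADDITIONAL_ELEMENTS: tuple[str, ...] = tuple(ADDITIONAL_CRITERIA)

_ZERO_LEVEL: dict[str, str] = {
    elem: next(tok for tok, (pts, _) in levels.items() if pts == 0)
    for elem, levels in ADDITIONAL_CRITERIA.items()
}


class AssessmentError(ValueError):
    """Invalid assessment document; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid assessment: " + "; ".join(errors))


@dataclass(frozen=True)
class BaseElementLevel:
    element: str
    level: str
    points: int
    description: str


@dataclass(frozen=True)
class AdditionalElementLevel:
    element: str
    level: str
    points: int
    description: str


@dataclass(frozen=True)
class ValueAssessment:
    """One drug's chosen criterion level for every value element."""

    drug_id: str
    base: Mapping[str, BaseElementLevel]
    additional: Mapping[str, AdditionalElementLevel]
    others_justification: str | None = None


def _base_level(element: str, level: str) -> BaseElementLevel:
    pts, desc = BASE_CRITERIA[element][level]
    return BaseElementLevel(element, level, pts, desc)


def _additional_level(element: str, level: str) -> AdditionalElementLevel:
    pts, desc = ADDITIONAL_CRITERIA[element][level]
    return AdditionalElementLevel(element, level, pts, desc)


def score_base(assessment: ValueAssessment) -> int:
    """Sum of the four base-element points (a multiple of 5 in [25, 50])."""
    missing = [e for e in BASE_ELEMENTS if e not in assessment.base]
    if missing:
        raise AssessmentError([f"missing base element: {e}" for e in missing])
    return sum(assessment.base[e].points for e in BASE_ELEMENTS)


def score_additional(assessment: ValueAssessment) -> int:
    """Sum of the eight additional-element points, in [0, 50]."""
    return sum(
        assessment.additional[e].points
        for e in ADDITIONAL_ELEMENTS
        if e in assessment.additional
    )


def validate_assessment(document: Mapping[str, Any]) -> ValueAssessment:
    """Turn a parsed assessment document into a :class:`ValueAssessment`.

    All violations are collected and reported together in the raised
    :class:`AssessmentError`, not just the first.

    The document is flat: ``drug_id`` plus one key per element whose value is
    the level token.  The "others" element alternatively takes a mapping
    ``{"level": ..., "justification": ...}``; a justification is mandatory
    when others is scored.
    """
    errors: list[str] = []
    if not isinstance(document, Mapping):
        raise AssessmentError(["assessment document must be a mapping"])

    drug_id = document.get("drug_id")
    if not isinstance(drug_id, str) or not drug_id:
        errors.append("missing or empty drug_id")
        drug_id = ""

    known = set(BASE_ELEMENTS) | set(ADDITIONAL_ELEMENTS) | {"drug_id"}
    for key in document:
        if key not in known:
            errors.append(f"unknown element: {key}")

    base: dict[str, BaseElementLevel] = {}
    for elem in BASE_ELEMENTS:
        if elem not in document:
            errors.append(f"missing base element: {elem}")
            continue
        level = document[elem]
        if level not in BASE_CRITERIA[elem]:
            errors.append(
                f"unknown level for {elem}: {level!r} "
                f"(expected one of {sorted(BASE_CRITERIA[elem])})")
            continue
        base[elem] = _base_level(elem, level)

    additional: dict[str, AdditionalElementLevel] = {}
    justification: str | None = None
    for elem in ADDITIONAL_ELEMENTS:
        raw = document.get(elem, _ZERO_LEVEL[elem])
        level = raw
        if elem == "others" and isinstance(raw, Mapping):
            level = raw.get("level")
            justification = raw.get("justification")
        if not isinstance(level, str) or level not in ADDITIONAL_CRITERIA[elem]:
            errors.append(
                f"unknown level for {elem}: {level!r} "
                f"(expected one of {sorted(ADDITIONAL_CRITERIA[elem])})")
            continue
        additional[elem] = _additional_level(elem, level)

    others = additional.get("others")
    if others is not None and others.points > 0 and not justification:
        errors.append("others scored 'applicable' requires a justification "
                      "(use others: {level: applicable, justification: ...})")

    if errors:
        raise AssessmentError(errors)
    return ValueAssessment(drug_id=drug_id, base=base, additional=additional,
                           others_justification=justification)
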