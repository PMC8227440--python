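"""The published 9-leaf decision tree for current MS phenotype.

The classifier assigns a patient's current phenotype — relapsing-remitting
(RR) or secondary progressive (SP) — from exactly two cross-sectional
inputs: the most recent EDSS score and the age at that assessment. It is a
fixed lookup over nine terminal rules; each rule carries the probability of
SPMS estimated in the Swedish MS registry training cohort, and the label is
SP exactly when that probability exceeds 0.5.

Age bands are half-open with the lower bound inclusive: the printed bands
"<56", "56-64" and ">=64" become [0, 56), [56, 64) and [64, inf), the only
reading that keeps them disjoint. Ages are real-valued by default; set
``floor_age=True`` to truncate to whole years as some registries store
them. EDSS membership is exact membership on the 0.5 grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data_model import (
    Cohort,
    RowError,
    ValidationConfig,
    age_at,
    latest_assessment,
    validate_edss,
)


@dataclass(frozen=True)
class PublishedRule:
    rule_id: str
    edss_values: frozenset[float]
    age_low: float  # inclusive
    age_high: float  # exclusive
    sp_probability: float
    label: str

    def matches(self, edss: float, age: float) -> bool:
        return edss in self.edss_values and self.age_low <= age < self.age_high


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    sp_probability: float
    matched_rule: PublishedRule


def _grid(low: float, high: float) -> frozenset[float]:
    """Valid EDSS grid values in [low, high]."""
    vals = [0.0] + [x / 2 for x in range(2, 21)]
    return frozenset(v for v in vals if low <= v <= high)


INF = math.inf

#: The nine terminal rules (EDSS set, [age_low, age_high), P(SPMS), label).
RULES: tuple[PublishedRule, ...] = (
    PublishedRule("edss_lt3", _grid(0.0, 2.5), 0.0, INF, 0.04, "RR"),
    PublishedRule("edss_3to4_age_lt56", frozenset({3.0, 3.5, 4.0}), 0.0, 56.0, 0.18, "RR"),
    PublishedRule("edss_4p5to6_age_lt45", frozenset({4.5, 5.0, 5.5, 6.0}), 0.0, 45.0, 0.38, "RR"),
    PublishedRule("edss_3or3p5_age_56to64", frozenset({3.0, 3.5}), 56.0, 64.0, 0.39, "RR"),
    PublishedRule("edss_3_age_ge64", frozenset({3.0}), 64.0, INF, 0.48, "RR"),
    PublishedRule("edss_4_age_56to64", frozenset({4.0}), 56.0, 64.0, 0.53, "SP"),
    PublishedRule("edss_3p5or4_age_ge64", frozenset({3.5, 4.0}), 64.0, INF, 0.61, "SP"),
    PublishedRule("edss_4p5to6_age_ge45", frozenset({4.5, 5.0, 5.5, 6.0}), 45.0, INF, 0.76, "SP"),
    PublishedRule("edss_gt6", _grid(6.5, 10.0), 0.0, INF, 0.93, "SP"),
)


def classify(
    edss: float,
    age: float,
    *,
    floor_age: bool = False,
    config: ValidationConfig | None = None,
) -> ClassificationResult:
    """Classify one (EDSS, age) pair against the published rule table.

    Deterministic: exactly one rule matches any valid input. Raises
    :class:`~msclassify.data_model.RowError` for an off-grid EDSS or a
    negative age.
    """
    edss = validate_edss(edss, config)
    if edss == 0.5:
        # permissive registries: no 0.5 leaf exists; fold into the <3 leaf
        edss = 0.0
    if age < 0:
        raise RowError(f"age must be nonnegative, got {age}")
    if floor_age:
        age = float(math.floor(age))
    matched = [r for r in RULES if r.matches(edss, age)]
    assert len(matched) == 1, f"rule table must partition the input space: {edss}, {age}"
    rule = matched[0]
    return ClassificationResult(label=rule.label, sp_probability=rule.sp_probability, matched_rule=rule)


def classify_cohort(
    cohort: Cohort, *, floor_age: bool = False
) -> tuple[dict[str, ClassificationResult], int]:
    """Classify every patient from their latest visit.

    Returns ``(results, n_excluded)`` where patients without any visit are
    excluded and counted rather than failing the whole cohort.
    """
    results: dict[str, ClassificationResult] = {}
    n_excluded = 0
    for p in cohort.patients:
        visits = cohort.visits_of(p.patient_id)
        if not visits:
            n_excluded += 1
            continue
        last = latest_assessment(visits)
        results[p.patient_id] = classify(
            last.edss, age_at(p, last.visit_date), floor_age=floor_age
        )
    return results, n_excluded
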