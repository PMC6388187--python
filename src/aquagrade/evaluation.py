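"""Composite fuzzy evaluation and maximum-membership grading.

The weight vector A and relation matrix R combine by the weighted-sum
composition b_m = Σ_i a_i r_im (ordinary matrix product, not the max-min
fuzzy operator), giving a composite membership vector B over the five
grades.  The well is assigned the grade holding the maximum composite
membership; exact ties resolve to the worse grade, the health-conservative
choice, and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InputDataError
from .membership import N_GRADES, RelationMatrix, build_relation_matrix
from .samples import WellSample
from .standards import FUZZY_INDICATORS, StandardsTable, grade_label
from .weighting import WeightVector, weights_for_sample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationVector:
    """One well's composite membership degrees, assigned grade, and audit trail."""

    well_id: str
    degrees: np.ndarray  # length 5
    grade: int  # 1..5
    relation: RelationMatrix | None = None
    weights: WeightVector | None = None

    @property
    def label(self) -> str:
        return grade_label(self.grade)

    def to_dict(self) -> dict:
        out = {
            "well_id": self.well_id,
            "degrees": [float(v) for v in self.degrees],
            "grade": self.grade,
            "label": self.label,
        }
        if self.relation is not None:
            out["relation_matrix"] = self.relation.to_dict()
        if self.weights is not None:
            out["weights"] = {
                code: float(w)
                for code, w in zip(self.weights.indicators, self.weights.normalized)
            }
            out["raw_weights"] = {
                code: float(w)
                for code, w in zip(self.weights.indicators, self.weights.raw)
            }
        return out


def compose(a: WeightVector, r: RelationMatrix) -> np.ndarray:
    """Weighted-sum composition B = A x R."""
    if a.indicators != r.indicators:
        raise InputDataError(
            "weight vector and relation matrix disagree on indicator order: "
            f"{a.indicators} vs {r.indicators}"
        )
    return a.normalized @ r.degrees


def classify(degrees) -> int:
    """Maximum-membership grade (1..5) of a composite vector; ties go worse."""
    b = np.asarray(degrees, dtype=float)
    if b.size != N_GRADES or not np.all(np.isfinite(b)):
        raise InputDataError(f"invalid composite membership vector: {degrees}")
    # argmax on the reversed vector returns the worst grade among exact ties
    worst_first = b[::-1]
    grade = N_GRADES - int(np.argmax(worst_first))
    if np.count_nonzero(b == b.max()) > 1:
        logger.info("tie in composite memberships %s resolved to grade %s", b, grade)
    return grade


def evaluate_well(
    sample: WellSample,
    standards: StandardsTable,
    order: tuple[str, ...] = FUZZY_INDICATORS,
) -> EvaluationVector:
    """Full fuzzy evaluation of one well: fuzzify, weight, compose, grade."""
    r = build_relation_matrix(sample, standards, order)
    a = weights_for_sample(sample, standards, order)
    b = compose(a, r)
    grade = classify(b)
    logger.debug("well %s: B=%s grade=%s", sample.well_id, b, grade)
    return EvaluationVector(
        well_id=sample.well_id, degrees=b, grade=grade, relation=r, weights=a
    )


def grade_distribution(results: list[EvaluationVector]) -> dict[int, float]:
    """Percentage of wells per grade (keys 1..5, values summing to 100)."""
    if not results:
        raise InputDataError("no evaluation results to summarize")
    counts = np.zeros(N_GRADES)
    for res in results:
        counts[res.grade - 1] += 1
    pct = 100.0 * counts / counts.sum()
    return {g + 1: float(pct[g]) for g in range(N_GRADES)}
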