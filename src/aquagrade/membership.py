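"""Fuzzification: crisp concentrations -> graded membership degrees.

Each indicator's measured value is mapped onto the five quality grades with
piecewise-linear (trapezoidal) membership functions built from the graded
class limits S1..S4:

* grade I keeps full membership up to S1 and ramps to 0 at S2;
* interior grades II-IV rise from 0 at the previous limit to 1 at their own
  limit and fall to 0 at the next one, so memberships of adjacent grades are
  complementary between consecutive limits;
* grade V, which is open-ended, is a step: 0 at or below S4, 1 above it.

Consequences used throughout the package: every membership row sums to
exactly 1, at most two entries are nonzero and they sit on adjacent grades,
and a boundary value belongs to the better grade's full-membership side.
Zero-width intervals (equal consecutive limits, e.g. ammonium's S1 = S2)
are skipped, with the shared point assigned to the more stringent grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError
from .samples import WellSample
from .standards import FUZZY_INDICATORS, GradedStandard, StandardsTable

N_GRADES = 5
GRADE_COLUMNS = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class TrapezoidParams:
    """Corners (alpha, beta, gamma, delta) of one trapezoidal fuzzy set.

    Membership is 0 outside [alpha, delta], 1 on [beta, gamma], and linear on
    the two ramps.  Infinite corners give one-sided shoulders.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.alpha <= self.beta <= self.gamma <= self.delta):
            raise ConfigurationError(
                f"trapezoid corners must ascend: {self}"
            )


def trapezoid_membership(x: float, p: TrapezoidParams) -> float:
    """Evaluate one trapezoidal membership function at *x*.

    Zero-width ramps (alpha == beta or gamma == delta) degenerate to steps
    whose shared point carries membership 1.
    """
    if x < p.alpha or x > p.delta:
        return 0.0
    if p.beta <= x <= p.gamma:
        return 1.0
    if x < p.beta:
        return (x - p.alpha) / (p.beta - p.alpha)
    return (p.delta - x) / (p.delta - p.gamma)


def grade_memberships(x: float, standard: GradedStandard) -> np.ndarray:
    """Membership of concentration *x* in each of the five quality grades.

    Returns a length-5 vector summing to 1 with at most two nonzero,
    adjacent entries.
    """
    if not math.isfinite(x):
        raise InputDataError(f"{standard.indicator}: non-finite concentration {x}")
    if x < 0:
        raise InputDataError(
            f"{standard.indicator}: negative concentration {x}"
        )
    s = standard.limits
    m = np.zeros(N_GRADES)
    if x <= s[0]:
        m[0] = 1.0
    elif x > s[3]:
        m[4] = 1.0
    else:
        # Exactly one half-open interval (S_j, S_{j+1}] contains x; empty
        # (zero-width) intervals are skipped automatically.
        for j in range(3):
            lo, hi = s[j], s[j + 1]
            if lo < x <= hi:
                t = (x - lo) / (hi - lo)
                m[j] = 1.0 - t
                m[j + 1] = t
                break
    return m


def grade_trapezoids(standard: GradedStandard) -> list[TrapezoidParams]:
    """The five explicit trapezoids equivalent to :func:`grade_memberships`.

    Provided for audit and cross-checking: evaluating grade *g*'s trapezoid
    at *x* reproduces ``grade_memberships(x, standard)[g]`` everywhere except
    at the isolated grade-IV/V boundary point S4, where the step convention
    keeps full membership with grade IV.
    """
    s1, s2, s3, s4 = standard.limits
    inf = math.inf
    return [
        TrapezoidParams(-inf, -inf, s1, s2),
        TrapezoidParams(s1, s2, s2, s3),
        TrapezoidParams(s2, s3, s3, s4),
        TrapezoidParams(s3, s4, s4, s4),
        TrapezoidParams(s4, s4, inf, inf),
    ]


@dataclass(frozen=True)
class RelationMatrix:
    """The fuzzy relation matrix R: indicators x grades membership degrees."""

    indicators: tuple[str, ...]
    degrees: np.ndarray  # shape (n, 5)

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=float)
        if d.shape != (len(self.indicators), N_GRADES):
            raise InputDataError(
                f"relation matrix shape {d.shape} does not match "
                f"{len(self.indicators)} indicators x {N_GRADES} grades"
            )
        object.__setattr__(self, "degrees", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.degrees, index=list(self.indicators), columns=list(GRADE_COLUMNS)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="indicator")

    def to_dict(self) -> dict[str, list[float]]:
        return {
            code: [float(v) for v in row]
            for code, row in zip(self.indicators, self.degrees)
        }


def build_relation_matrix(
    sample: WellSample,
    standards: StandardsTable,
    order: tuple[str, ...] = FUZZY_INDICATORS,
) -> RelationMatrix:
    """Fuzzify one well against the graded standard, row per indicator."""
    sample.require(order)
    rows = [grade_memberships(sample[code], standards[code]) for code in order]
    return RelationMatrix(indicators=tuple(order), degrees=np.array(rows))
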