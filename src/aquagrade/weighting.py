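"""Over-standard weighting of evaluation factors.

Each indicator's raw weight is its measured concentration divided by the
mean of its five class limits, W_i = C_i / S̄_i, so indicators running close
to (or beyond) their standards dominate the composite evaluation.  Raw
weights are normalized to sum to one: a_i = W_i / Σ W_i.  Concentrations
above the grade-IV limit are deliberately not capped — a heavily exceeding
indicator should carry proportionally heavy weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError
from .samples import WellSample
from .standards import FUZZY_INDICATORS, StandardsTable, class_mean_limit

_SUM_TOL = 1e-12


def raw_weight(c: float, s_bar: float) -> float:
    """Unnormalized over-standard weight W = C / S̄."""
    if s_bar <= 0:
        raise ConfigurationError(f"degenerate class-mean limit {s_bar}")
    if c < 0:
        raise InputDataError(f"negative concentration {c}")
    return c / s_bar


@dataclass(frozen=True)
class WeightVector:
    """Normalized indicator weights plus the raw W_i they came from."""

    indicators: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        norm = np.asarray(self.normalized, dtype=float)
        if raw.shape != norm.shape or raw.shape != (len(self.indicators),):
            raise InputDataError("weight vector shape mismatch")
        if abs(norm.sum() - 1.0) > 1e-9:
            raise InputDataError("normalized weights do not sum to 1")
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "normalized", norm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_weight": self.raw, "weight": self.normalized},
            index=list(self.indicators),
        )


def normalize_weights(
    raws, indicators: tuple[str, ...] | None = None
) -> WeightVector:
    """Normalize raw weights to the unit simplex."""
    raw = np.asarray(list(raws), dtype=float)
    if raw.size == 0 or not np.all(np.isfinite(raw)) or np.any(raw < 0):
        raise InputDataError("raw weights must be finite and nonnegative")
    total = raw.sum()
    if total <= _SUM_TOL:
        raise InputDataError(
            "all raw weights are zero; the weight vector is undefined"
        )
    if indicators is None:
        indicators = tuple(f"u{i + 1}" for i in range(raw.size))
    return WeightVector(
        indicators=tuple(indicators), raw=raw, normalized=raw / total
    )


def weights_for_sample(
    sample: WellSample,
    standards: StandardsTable,
    order: tuple[str, ...] = FUZZY_INDICATORS,
) -> WeightVector:
    """Over-standard weight vector for one well, in the given indicator order."""
    sample.require(order)
    raws = [
        raw_weight(sample[code], class_mean_limit(standards[code]))
        for code in order
    ]
    return normalize_weights(raws, indicators=tuple(order))
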