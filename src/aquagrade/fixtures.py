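"""Published worked-example fixtures.

The study underlying this package printed, for one well (Q6), the full
fuzzy relation matrix and normalized weight vector, and for all six wells
the composite membership vectors with their assigned grades and Piper
water types.  Those printed values ship here read-only so every pipeline
stage can be exercised and cross-checked without any external data.

The printed relation matrix's row order was not stated by its source; rows
are carried in the canonical nine-indicator order, and users should treat
per-row identities as indicative only (the first row is not consistent with
the published TH range under any linear convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .membership import RelationMatrix
from .standards import StandardsTable, builtin_drinking_limits, builtin_graded_standard
from .synthetic import published_stats
from .weighting import WeightVector


@dataclass(frozen=True)
class FixtureSet:
    """Read-only bundle of the published worked-example values."""

    indicator_order: tuple[str, ...]
    q6_relation: RelationMatrix
    q6_weights: WeightVector
    q6_composite: np.ndarray
    q6_grade: int
    panel_degrees: dict[str, np.ndarray]  # well -> printed composite vector
    panel_grades: dict[str, int]
    facies_labels: dict[str, str]
    graded_standard: StandardsTable
    stats: pd.DataFrame
    who_limits: dict
    gb_limits: dict


def load_fixtures() -> FixtureSet:
    """Load the published fixtures shipped with the package."""
    path = resources.files("aquagrade").joinpath("data", "published_example.json")
    with open(str(path)) as fh:
        blob = json.load(fh)
    order = tuple(blob["indicator_order"])
    q6 = blob["q6"]
    relation = RelationMatrix(
        indicators=order, degrees=np.array(q6["relation"], dtype=float)
    )
    raw = np.array(q6["weights"], dtype=float)
    weights = WeightVector(
        indicators=order, raw=raw, normalized=raw / raw.sum()
    )
    return FixtureSet(
        indicator_order=order,
        q6_relation=relation,
        q6_weights=weights,
        q6_composite=np.array(q6["composite"], dtype=float),
        q6_grade=int(q6["grade"]),
        panel_degrees={
            well: np.array(entry["degrees"], dtype=float)
            for well, entry in blob["panel"].items()
        },
        panel_grades={
            well: int(entry["grade"]) for well, entry in blob["panel"].items()
        },
        facies_labels=dict(blob["facies_labels"]),
        graded_standard=builtin_graded_standard(),
        stats=published_stats(),
        who_limits=builtin_drinking_limits("WHO2011"),
        gb_limits=builtin_drinking_limits("GB5749"),
    )
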