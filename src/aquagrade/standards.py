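"""Water-quality standards registry.

Three standards drive the pipeline:

* the five-grade Chinese groundwater standard GB/T 14848-93, whose four
  ascending class limits S1..S4 per indicator bound grades I..IV (grade V is
  the open interval above S4);
* the WHO (2011) and Chinese drinking-water (GB 5749-2006) single limits used
  for compliance flagging;
* per-indicator class-mean limits, the denominator of the over-standard
  weighting scheme.

The built-in tables ship as plain CSV inside the package and can be replaced
by user files of the same layout, so other national standards drop in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Registered indicator codes and their fixed units.
INDICATOR_UNITS: dict[str, str] = {
    "pH": "-",
    "EC": "uS/cm",
    "TH": "mg/L",
    "TDS": "mg/L",
    "Na": "mg/L",
    "K": "mg/L",
    "Ca": "mg/L",
    "Mg": "mg/L",
    "HCO3": "mg/L",
    "Cl": "mg/L",
    "SO4": "mg/L",
    "NO2": "mg/L",
    "NO3": "mg/L",
    "NH4": "mg/L",
    "Mn": "mg/L",
    "Fe": "mg/L",
}

#: The nine indicators entering the fuzzy evaluation, in canonical row order.
FUZZY_INDICATORS: tuple[str, ...] = (
    "TH", "TDS", "NO2", "NO3", "NH4", "Mn", "Fe", "Cl", "SO4",
)

#: Grade descriptors, 1-based.
GRADE_DESCRIPTORS: dict[int, str] = {
    1: "excellent",
    2: "good",
    3: "moderate",
    4: "poor",
    5: "very poor",
}

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}

STANDARDS_VERSION = "GB/T 14848-93 (nine-indicator table)"


@dataclass(frozen=True)
class GradedStandard:
    """Five-grade class limits for one indicator.

    ``limits`` holds the four ascending boundaries (S1, S2, S3, S4); grade V
    is open-ended (``> S4``) and carries no numeric upper limit.
    """

    indicator: str
    unit: str
    limits: tuple[float, float, float, float]
    grade_v_open: bool = True

    def __post_init__(self) -> None:
        s = self.limits
        if len(s) != 4:
            raise ConfigurationError(
                f"{self.indicator}: expected four class limits, got {len(s)}"
            )
        if any(v < 0 for v in s):
            raise ConfigurationError(f"{self.indicator}: negative class limit")
        if not (s[0] <= s[1] <= s[2] <= s[3]):
            raise ConfigurationError(
                f"{self.indicator}: class limits must ascend, got {s}"
            )


class StandardsTable:
    """An ordered mapping indicator -> :class:`GradedStandard`."""

    def __init__(self, standards: list[GradedStandard]):
        self._by_code: dict[str, GradedStandard] = {}
        for s in standards:
            if s.indicator in self._by_code:
                raise ConfigurationError(f"duplicate standard for {s.indicator}")
            self._by_code[s.indicator] = s

    def __getitem__(self, code: str) -> GradedStandard:
        try:
            return self._by_code[code]
        except KeyError:
            raise ConfigurationError(
                f"no graded standard registered for indicator {code!r}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self._by_code)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"indicator": s.indicator, "unit": s.unit,
             "S1": s.limits[0], "S2": s.limits[1],
             "S3": s.limits[2], "S4": s.limits[3]}
            for s in self
        ]
        return pd.DataFrame(rows, columns=["indicator", "unit", "S1", "S2", "S3", "S4"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StandardsTable":
        standards = [
            GradedStandard(
                indicator=str(row["indicator"]),
                unit=str(row["unit"]),
                limits=(float(row["S1"]), float(row["S2"]),
                        float(row["S3"]), float(row["S4"])),
            )
            for _, row in frame.iterrows()
        ]
        return cls(standards)

    @classmethod
    def from_csv(cls, path) -> "StandardsTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class DrinkingLimit:
    """A single drinking-water limit: an upper bound, or a closed range (pH)."""

    indicator: str
    scheme: str
    lower: float | None
    upper: float

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ConfigurationError(
                f"{self.indicator}/{self.scheme}: nonpositive limit"
            )
        if self.lower is not None and self.lower > self.upper:
            raise ConfigurationError(
                f"{self.indicator}/{self.scheme}: range bounds must ascend"
            )

    @property
    def is_range(self) -> bool:
        return self.lower is not None

    def within(self, value: float) -> bool:
        if self.is_range:
            return self.lower <= value <= self.upper
        return value <= self.upper


DRINKING_SCHEMES = ("WHO2011", "GB5749")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("aquagrade").joinpath("data", name)))


def builtin_graded_standard(path=None) -> StandardsTable:
    """The built-in GB/T 14848-93 nine-indicator table (or a drop-in file)."""
    if path is not None and not Path(path).exists():
        raise ConfigurationError(f"graded-standard file not found: {path}")
    table = StandardsTable.from_csv(path or _data_path("gb_t_14848_93.csv"))
    if path is None and set(table.indicators) != set(FUZZY_INDICATORS):
        raise ConfigurationError("packaged graded-standard table is corrupt")
    return table


def builtin_drinking_limits(scheme: str, path=None) -> dict[str, DrinkingLimit]:
    """Single drinking limits for one scheme (``WHO2011`` or ``GB5749``).

    Indicators without a printed limit under a scheme are absent from the
    returned mapping, not unlimited.
    """
    if scheme not in DRINKING_SCHEMES:
        raise ConfigurationError(
            f"unknown drinking-water scheme {scheme!r}; choose from {DRINKING_SCHEMES}"
        )
    frame = pd.read_csv(path or _data_path("drinking_limits.csv"))
    out: dict[str, DrinkingLimit] = {}
    for _, row in frame[frame["scheme"] == scheme].iterrows():
        lower = None if pd.isna(row["lower"]) else float(row["lower"])
        out[str(row["indicator"])] = DrinkingLimit(
            indicator=str(row["indicator"]), scheme=scheme,
            lower=lower, upper=float(row["upper"]),
        )
    return out


def class_mean_limit(standard: GradedStandard, s5: float | None = None) -> float:
    """Mean of the five class limits, the weighting denominator S̄.

    Grade V has no printed upper bound, so its limit S5 defaults to S4 (the
    shared grade-IV/V boundary); pass ``s5`` to override.
    """
    s1, s2, s3, s4 = standard.limits
    if s5 is None:
        s5 = s4
    return (s1 + s2 + s3 + s4 + s5) / 5.0


def grade_label(grade: int) -> str:
    """Human-readable label, e.g. ``'II (good)'``."""
    return f"{ROMAN[grade]} ({GRADE_DESCRIPTORS[grade]})"
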