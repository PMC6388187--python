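"""Synthetic well panels with the statistical structure the analysis assumes.

No per-well raw chemistry accompanies the published study, so this module
generates panels calibrated to the published per-indicator summary
statistics: each indicator is drawn from a truncated normal with the
published mean and standard deviation, hard-truncated at the published
min/max (or from a uniform on [min, max], since a six-well panel makes the
normality assumption weak).  Seasonal monitoring is emulated by drawing a
configurable number of replicates per well (default 4, matching quarterly
sampling) and averaging them.  Indicators are drawn independently — the
strong inter-ion correlations of real groundwater are deliberately not
modeled, which matters mostly for joint-extreme behavior.

``plant_grade_scenario`` builds wells whose indicators all sit inside a
chosen quality grade, for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UnplantableScenarioError
from .samples import WellSample
from .standards import StandardsTable

DEFAULT_REPLICATES = 4


@dataclass(frozen=True)
class IndicatorDistribution:
    """Sampling law for one indicator: truncated normal or uniform on [lo, hi]."""

    kind: str  # "truncnorm" | "uniform"
    lo: float
    hi: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("truncnorm", "uniform"):
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        if self.lo > self.hi:
            raise ConfigurationError(f"lo {self.lo} > hi {self.hi}")
        if self.kind == "truncnorm":
            if self.mean is None or self.sd is None or self.sd < 0:
                raise ConfigurationError("truncnorm needs mean and sd >= 0")
            if self.sd == 0 and not self.lo <= self.mean <= self.hi:
                raise ConfigurationError(
                    f"degenerate distribution with mean {self.mean} outside "
                    f"[{self.lo}, {self.hi}]"
                )
            if self.sd > 0:
                # Infeasible truncation: the window carries essentially no mass.
                a = (self.lo - self.mean) / self.sd
                b = (self.hi - self.mean) / self.sd
                if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
                    raise ConfigurationError(
                        f"infeasible truncation: mean {self.mean}, sd {self.sd} "
                        f"on [{self.lo}, {self.hi}]"
                    )

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size=size)
        if self.sd == 0 or self.lo == self.hi:
            return np.full(size, float(np.clip(self.mean, self.lo, self.hi)))
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Panel-generation settings: per-indicator laws, size, replication, seed."""

    distributions: dict[str, IndicatorDistribution]
    n_wells: int = 6
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    well_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ConfigurationError("n_wells must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def published_stats() -> pd.DataFrame:
    """The published per-indicator min/max/mean/sd table (calibration source)."""
    path = resources.files("aquagrade").joinpath("data", "indicator_stats.csv")
    return pd.read_csv(str(path), index_col="indicator")


def default_config(
    n_wells: int = 6,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    kind: str = "truncnorm",
) -> GeneratorConfig:
    """Generator calibrated to the published descriptive statistics."""
    table = published_stats()
    dists = {
        code: IndicatorDistribution(
            kind=kind,
            lo=float(row["min"]),
            hi=float(row["max"]),
            mean=float(row["mean"]),
            sd=float(row["sd"]),
        )
        for code, row in table.iterrows()
    }
    return GeneratorConfig(
        distributions=dists, n_wells=n_wells, replicates=replicates, seed=seed
    )


def generate_panel(config: GeneratorConfig) -> list[WellSample]:
    """Draw a panel of synthetic wells; deterministic given ``config.seed``.

    Each well's value for an indicator is the mean of ``config.replicates``
    independent draws; every underlying draw respects the truncation bounds,
    so the averaged values do too.
    """
    rng = np.random.default_rng(config.seed)
    per_well = {
        code: dist.draw(rng, (config.n_wells, config.replicates)).mean(axis=1)
        for code, dist in config.distributions.items()
    }
    return [
        WellSample(
            well_id=f"{config.well_prefix}{w + 1}",
            values={code: float(col[w]) for code, col in per_well.items()},
        )
        for w in range(config.n_wells)
    ]


def _planting_interval(
    limits: tuple[float, float, float, float], grade: int
) -> tuple[float, float]:
    """Open interval of concentrations that a planted grade is drawn from.

    Grade I uses (0, S1) where its membership is 1; grade V uses (S4, 2*S4).
    For interior grades the draw is restricted to the half of the class
    interval adjoining the grade's own limit, where that grade's membership
    strictly exceeds one half, so the planted grade is the modal grade of
    every fuzzified row and recovery is exact by construction.
    """
    s1, s2, s3, s4 = limits
    if grade == 1:
        lo, hi = 0.0, s1
    elif grade == 5:
        lo, hi = s4, 2.0 * s4
    else:
        lo, hi = limits[grade - 2], limits[grade - 1]
        if lo < hi:
            lo = 0.5 * (lo + hi)
    if not lo < hi:
        raise UnplantableScenarioError(
            f"grade {grade} has a zero-width class interval ({lo}, {hi})"
        )
    return lo, hi


def plant_grade_scenario(
    standards: StandardsTable,
    targets: dict[str, int],
    rng: np.random.Generator | int | None = 0,
    well_id: str = "planted",
) -> WellSample:
    """A well whose listed indicators are drawn inside their target grades.

    ``targets`` maps indicator code to a grade 1..5.  A zero-width target
    interval (e.g. ammonium's coinciding grade-I/II limits) raises
    :class:`UnplantableScenarioError`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = {}
    for code, grade in targets.items():
        if grade not in (1, 2, 3, 4, 5):
            raise ConfigurationError(f"{code}: target grade must be 1..5, got {grade}")
        lo, hi = _planting_interval(standards[code].limits, grade)
        # open interval: resample the (measure-zero) endpoints away
        x = rng.uniform(lo, hi)
        while not lo < x < hi:
            x = rng.uniform(lo, hi)
        values[code] = float(x)
    return WellSample(well_id=well_id, values=values)
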