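"""Traditional hydrochemical characterization of a well panel.

Descriptive statistics, the scalar classification rules for pH / electrical
conductivity / total hardness / total dissolved solids, per-scheme drinking
limit compliance, and Pearson correlation with two-tailed significance.
All classification boundaries are half-open with the boundary point in the
lower (less mineralized) class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDataError, InsufficientDataError
from .samples import WellSample
from .standards import DrinkingLimit

logger = logging.getLogger(__name__)

#: Half-width of the band around 7 that still counts as neutral pH.
NEUTRAL_PH_BAND = 0.2


def panel_frame(samples: list[WellSample]) -> pd.DataFrame:
    """Wells x indicators table (NaN where a well lacks an indicator)."""
    if not samples:
        raise InputDataError("empty well panel")
    ids = [s.well_id for s in samples]
    if len(set(ids)) != len(ids):
        raise InputDataError("duplicate well_id in panel")
    return pd.DataFrame([s.values for s in samples], index=ids)


def summary_stats(samples: list[WellSample], ddof: int = 1) -> pd.DataFrame:
    """Per-indicator Min / Max / Mean / Std. Deviation over the panel.

    The standard deviation uses the sample (n-1) denominator by default.
    """
    frame = panel_frame(samples)
    out = pd.DataFrame(
        {
            "Min": frame.min(),
            "Max": frame.max(),
            "Mean": frame.mean(),
            "Std. Deviation": frame.std(ddof=ddof).fillna(0.0),
        }
    )
    out.index.name = "indicator"
    return out


def classify_hardness(th: float) -> str:
    """Hardness class from total hardness in mg/L as CaCO3."""
    if th < 0:
        raise InputDataError(f"negative hardness {th}")
    if th <= 75:
        return "soft"
    if th <= 150:
        return "moderately hard"
    if th <= 300:
        return "hard"
    return "very hard"


def classify_tds(tds: float) -> str:
    """Salinity class from total dissolved solids in mg/L."""
    if tds < 0:
        raise InputDataError(f"negative TDS {tds}")
    if tds <= 1_000:
        return "fresh"
    if tds <= 10_000:
        return "brackish"
    if tds <= 1_000_000:
        return "saline"
    return "brine"


def classify_ec(ec: float) -> str:
    """Salt-enrichment type from electrical conductivity in uS/cm."""
    if ec < 0:
        raise InputDataError(f"negative conductivity {ec}")
    if ec <= 1_500:
        return "type I"
    if ec <= 3_000:
        return "type II"
    return "type III"


def classify_ph(ph: float, band: float = NEUTRAL_PH_BAND) -> str:
    """Acidic / neutral / alkaline, with ``neutral`` a band 7 +/- *band*."""
    if not 0 < ph < 14:
        raise InputDataError(f"pH {ph} outside (0, 14)")
    if ph < 7 - band:
        return "acidic"
    if ph > 7 + band:
        return "alkaline"
    return "neutral"


def compliance_flags(
    sample: WellSample, limits: dict[str, DrinkingLimit]
) -> dict[str, str]:
    """'within'/'exceeds' per indicator that has a limit under the scheme.

    Indicators with no limit in the scheme are skipped with a logged notice;
    range limits (pH) flag 'exceeds' on either side of the range.
    """
    flags: dict[str, str] = {}
    for code, value in sample.values.items():
        limit = limits.get(code)
        if limit is None:
            logger.info(
                "well %s: no limit for %s under this scheme; skipped",
                sample.well_id, code,
            )
            continue
        flags[code] = "within" if limit.within(value) else "exceeds"
    return flags


@dataclass
class CorrelationMatrix:
    """Pearson r with two-tailed p-values and strength labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    undefined: list[str] = field(default_factory=list)

    def significance(self, alpha: float) -> pd.DataFrame:
        return self.p < alpha

    def markers(self) -> pd.DataFrame:
        """'**' at the 0.01 level, '*' at 0.05, '' otherwise."""
        def mark(p: float) -> str:
            if np.isnan(p):
                return ""
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""

        return self.p.map(mark)

    @staticmethod
    def strength(r: float) -> str:
        """Strong above |r| = 0.7, moderate 0.5-0.7, weak below 0.5."""
        a = abs(r)
        if a > 0.7:
            return "strong"
        if a >= 0.5:
            return "moderate"
        return "weak"


def pearson_matrix(samples: list[WellSample]) -> CorrelationMatrix:
    """Pearson correlation over the panel's indicators.

    Requires at least three wells.  Indicators with zero variance are
    reported in ``undefined`` and carry NaN rows/columns rather than
    propagating numerical noise.
    """
    frame = panel_frame(samples)
    n = len(frame)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 wells for correlation, got {n}"
        )
    cols = list(frame.columns)
    undefined = [c for c in cols if np.isclose(frame[c].std(ddof=0), 0.0)]
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            if ci in undefined or cj in undefined:
                continue
            if ci == cj:
                r.loc[ci, cj], p.loc[ci, cj] = 1.0, 0.0
                continue
            res = stats.pearsonr(frame[ci], frame[cj])
            r.loc[ci, cj] = r.loc[cj, ci] = float(res.statistic)
            p.loc[ci, cj] = p.loc[cj, ci] = float(res.pvalue)
    if undefined:
        logger.info("zero-variance indicators, correlation undefined: %s", undefined)
    return CorrelationMatrix(r=r, p=p, undefined=undefined)
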