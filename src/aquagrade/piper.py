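"""Piper trilinear coordinates and hydrochemical facies.

Major-ion concentrations (mg/L) are converted to milliequivalents per liter,
expressed as percentages of total cations (Ca, Mg, Na+K pooled) and anions
(HCO3, SO4, Cl), plotted as barycentric points on the two ternary fields,
and projected into the central diamond, whose position depends only on the
alkali share (Na+K)% and the strong-acid share (SO4+Cl)%.  A water-type
label (e.g. ``Ca-HCO3``) lists every ion holding at least 20% of its
triangle's milliequivalents, in descending order of share.

Planar layout (fixed so plots are bit-reproducible): unit-edge equilateral
triangles with the cation triangle spanning x in [0, 1] (Ca at the origin,
Na+K at (1, 0), Mg at the apex) and the anion triangle x in [1.1, 2.1]
(HCO3 lower-left, Cl lower-right, SO4 apex); the diamond point is the
intersection of the 60-degree projection up-right from the cation point with
the 120-degree projection up-left from the anion point, placing the diamond
centered above the inter-triangle gap with the Ca-HCO3 corner on its left.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateSampleError, InputDataError
from .samples import WellSample

#: Equivalent weights in mg per meq (atomic/formula mass over charge).
EQUIVALENT_WEIGHTS: dict[str, float] = {
    "Ca": 20.04,
    "Mg": 12.15,
    "Na": 22.99,
    "K": 39.10,
    "HCO3": 61.02,
    "Cl": 35.45,
    "SO4": 48.03,
}

MAJOR_IONS = tuple(EQUIVALENT_WEIGHTS)
CATIONS = ("Ca", "Mg", "Na", "K")
ANIONS = ("HCO3", "SO4", "Cl")

_EDGE = 1.0
_GAP = 0.1
_H = np.sqrt(3.0) / 2.0  # height of a unit equilateral triangle
_ANION_OFFSET = _EDGE + _GAP

#: Facies label includes every ion with at least this share of its triangle.
FACIES_THRESHOLD_PCT = 20.0


def to_meq(c: float, ion: str) -> float:
    """Convert a concentration in mg/L to meq/L."""
    try:
        ew = EQUIVALENT_WEIGHTS[ion]
    except KeyError:
        raise ConfigurationError(
            f"no equivalent weight registered for ion {ion!r}"
        ) from None
    if c < 0:
        raise InputDataError(f"negative concentration {c} for {ion}")
    return c / ew


@dataclass(frozen=True)
class IonEquivalents:
    """meq/L of the seven major ions plus triangle percentages."""

    meq: dict[str, float]
    cation_total: float
    anion_total: float
    cation_pct: dict[str, float]  # keys Ca, Mg, NaK — sum to 100
    anion_pct: dict[str, float]  # keys HCO3, SO4, Cl — sum to 100


def ion_percentages(sample: WellSample) -> IonEquivalents:
    """Milliequivalent percentages for the Piper triangles.

    Na and K are pooled on the cation triangle, as the alkali vertex.
    """
    sample.require(MAJOR_IONS)
    meq = {ion: to_meq(sample[ion], ion) for ion in MAJOR_IONS}
    cation_total = sum(meq[i] for i in CATIONS)
    anion_total = sum(meq[i] for i in ANIONS)
    if cation_total <= 0 or anion_total <= 0:
        raise DegenerateSampleError(
            f"well {sample.well_id!r}: all-zero cations or anions"
        )
    cation_pct = {
        "Ca": 100.0 * meq["Ca"] / cation_total,
        "Mg": 100.0 * meq["Mg"] / cation_total,
        "NaK": 100.0 * (meq["Na"] + meq["K"]) / cation_total,
    }
    anion_pct = {ion: 100.0 * meq[ion] / anion_total for ion in ANIONS}
    return IonEquivalents(
        meq=meq,
        cation_total=cation_total,
        anion_total=anion_total,
        cation_pct=cation_pct,
        anion_pct=anion_pct,
    )


@dataclass(frozen=True)
class PiperCoordinates:
    """Barycentric and planar coordinates of one sample on the Piper diagram."""

    cation_bary: tuple[float, float, float]  # (Ca, NaK, Mg) shares, sum 1
    anion_bary: tuple[float, float, float]  # (HCO3, Cl, SO4) shares, sum 1
    diamond_shares: tuple[float, float]  # ((Na+K) share, (SO4+Cl) share)
    cation_xy: tuple[float, float]
    anion_xy: tuple[float, float]
    diamond_xy: tuple[float, float]


def piper_coordinates(shares: IonEquivalents) -> PiperCoordinates:
    """Planar Piper point from milliequivalent percentages (layout above)."""
    ca, mg, nak = (shares.cation_pct[k] / 100.0 for k in ("Ca", "Mg", "NaK"))
    hco3, so4, cl = (shares.anion_pct[k] / 100.0 for k in ("HCO3", "SO4", "Cl"))
    cation_xy = (nak + 0.5 * mg, _H * mg)
    anion_xy = (_ANION_OFFSET + cl + 0.5 * so4, _H * so4)
    # Intersection of the two 60-degree projections; depends only on the
    # alkali share p and the strong-acid share q.
    p, q = nak, so4 + cl
    diamond_xy = ((p + q + _ANION_OFFSET) / 2.0, _H * (_ANION_OFFSET + q - p))
    return PiperCoordinates(
        cation_bary=(ca, nak, mg),
        anion_bary=(hco3, cl, so4),
        diamond_shares=(p, q),
        cation_xy=cation_xy,
        anion_xy=anion_xy,
        diamond_xy=diamond_xy,
    )


def classify_facies(
    shares: IonEquivalents, threshold_pct: float = FACIES_THRESHOLD_PCT
) -> str:
    """Water-type label, e.g. ``Ca-HCO3`` or ``Ca-HCO3-SO4``.

    Every cation (Ca, Mg, pooled Na) and anion (HCO3, SO4, Cl) holding at
    least *threshold_pct* percent of its triangle's milliequivalents is
    listed, cations first, each group in descending order of share.
    """
    cation_names = {"Ca": "Ca", "Mg": "Mg", "NaK": "Na"}
    cations = sorted(
        ((pct, cation_names[k]) for k, pct in shares.cation_pct.items()),
        key=lambda t: -t[0],
    )
    anions = sorted(
        ((pct, k) for k, pct in shares.anion_pct.items()), key=lambda t: -t[0]
    )
    tokens = [name for pct, name in cations if pct >= threshold_pct]
    tokens += [name for pct, name in anions if pct >= threshold_pct]
    return "-".join(tokens)


def facies_distribution(labels: list[str]) -> dict[str, float]:
    """Percentage of wells per water type, summing to 100."""
    if not labels:
        raise InputDataError("no facies labels to summarize")
    counts = Counter(labels)
    n = len(labels)
    return {label: 100.0 * c / n for label, c in counts.most_common()}


def plot_piper(coordinates: list[PiperCoordinates], labels=None, ax=None):
    """Render the Piper diagram with matplotlib; returns the axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    d = _ANION_OFFSET
    tri_c = [(0, 0), (1, 0), (0.5, _H), (0, 0)]
    tri_a = [(d, 0), (d + 1, 0), (d + 0.5, _H), (d, 0)]
    diamond = [
        (0.5 + d / 2, _H * d),  # left  (Ca+Mg / HCO3)
        ((2 + d) / 2, _H * d),  # right (Na+K / SO4+Cl)
        ((1 + d) / 2, _H * (d + 1)),  # top
        ((1 + d) / 2, _H * (d - 1)),  # bottom
    ]
    for poly in (tri_c, tri_a):
        xs, ys = zip(*poly)
        ax.plot(xs, ys, color="black", lw=0.8)
    order = [diamond[0], diamond[2], diamond[1], diamond[3], diamond[0]]
    xs, ys = zip(*order)
    ax.plot(xs, ys, color="black", lw=0.8)
    for text, xy in [
        ("Ca", (0, -0.05)), ("Na+K", (1, -0.05)), ("Mg", (0.5, _H + 0.03)),
        ("HCO3", (d, -0.05)), ("Cl", (d + 1, -0.05)), ("SO4", (d + 0.5, _H + 0.03)),
    ]:
        ax.annotate(text, xy, ha="center", fontsize=8)
    for i, c in enumerate(coordinates):
        label = labels[i] if labels else None
        for xy in (c.cation_xy, c.anion_xy, c.diamond_xy):
            ax.plot(*xy, marker="o", ms=4, color=f"C{i % 10}")
        if label:
            ax.annotate(label, c.diamond_xy, fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
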