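"""Milliequivalent conversion, Piper coordinates, facies labels."""

import math

import numpy as np
import pytest

import aquagrade as aq
from aquagrade.piper import EQUIVALENT_WEIGHTS, _H


def sample_from_meq(well_id="w", **meq):
    """Build a WellSample whose mg/L values yield the requested meq/L."""
    values = {ion: meq.get(ion, 0.0) * EQUIVALENT_WEIGHTS[ion]
              for ion in EQUIVALENT_WEIGHTS}
    return aq.WellSample(well_id, values)


class TestToMeq:
    @pytest.mark.parametrize(
        "ion, mg, expected",
        [("Ca", 100.2, 5.0), ("Na", 22.99, 1.0), ("Cl", 0.0, 0.0),
         ("Mg", 24.30, 2.0), ("SO4", 96.06, 2.0)],
    )
    def test_equivalent_weight_conversion(self, ion, mg, expected):
        assert aq.to_meq(mg, ion) == pytest.approx(expected, rel=1e-3)

    def test_unknown_ion_is_a_configuration_error(self):
        with pytest.raises(aq.ConfigurationError):
            aq.to_meq(1.0, "PO4")

    def test_linearity(self):
        assert aq.to_meq(10.0, "Cl") == pytest.approx(10 * aq.to_meq(1.0, "Cl"))


class TestIonPercentages:
    def test_equal_cation_equivalents_split_evenly(self):
        s = sample_from_meq(Ca=2.0, Mg=2.0, Na=1.0, K=1.0, HCO3=1.0)
        shares = aq.ion_percentages(s)
        assert shares.cation_pct["Ca"] == pytest.approx(100 / 3, rel=1e-6)
        assert shares.cation_pct["Mg"] == pytest.approx(100 / 3, rel=1e-6)
        assert shares.cation_pct["NaK"] == pytest.approx(100 / 3, rel=1e-6)

    def test_single_anion_takes_all(self):
        s = sample_from_meq(Ca=1.0, HCO3=4.0)
        shares = aq.ion_percentages(s)
        assert shares.anion_pct == pytest.approx(
            {"HCO3": 100.0, "SO4": 0.0, "Cl": 0.0}
        )

    def test_hand_computed_shares(self):
        s = sample_from_meq(Ca=5.0, Mg=2.5, Na=2.0, K=0.5, HCO3=1.0)
        shares = aq.ion_percentages(s)
        assert shares.cation_pct["Ca"] == pytest.approx(50.0)
        assert shares.cation_pct["Mg"] == pytest.approx(25.0)
        assert shares.cation_pct["NaK"] == pytest.approx(25.0)

    def test_totals_sum_to_one_hundred(self, six_well_panel):
        for s in six_well_panel:
            shares = aq.ion_percentages(s)
            assert sum(shares.cation_pct.values()) == pytest.approx(100.0)
            assert sum(shares.anion_pct.values()) == pytest.approx(100.0)

    def test_all_zero_cations_rejected(self):
        with pytest.raises(aq.DegenerateSampleError):
            aq.ion_percentages(sample_from_meq(HCO3=1.0))

    def test_missing_major_ion_is_incomplete(self):
        s = aq.WellSample("w", {"Ca": 10.0})
        with pytest.raises(aq.IncompleteSampleError):
            aq.ion_percentages(s)


class TestPiperCoordinates:
    def test_calcium_bicarbonate_vertex_case(self):
        shares = aq.ion_percentages(sample_from_meq(Ca=3.0, HCO3=3.0))
        c = aq.piper_coordinates(shares)
        assert c.cation_xy == pytest.approx((0.0, 0.0))  # Ca vertex
        assert c.anion_xy == pytest.approx((1.1, 0.0))  # HCO3 vertex
        assert c.diamond_shares == pytest.approx((0.0, 0.0))  # diamond origin
        # geometrically the Ca+Mg / HCO3 corner of the diamond
        assert c.diamond_xy == pytest.approx((0.55, _H * 1.1))

    def test_centroid_case(self):
        shares = aq.ion_percentages(
            sample_from_meq(Ca=1, Mg=1, Na=1, HCO3=1, SO4=1, Cl=1)
        )
        c = aq.piper_coordinates(shares)
        assert c.cation_bary == pytest.approx((1 / 3,) * 3)
        assert c.anion_bary == pytest.approx((1 / 3,) * 3)
        assert c.cation_xy == pytest.approx((0.5, _H / 3))
        assert c.anion_xy == pytest.approx((1.6, _H / 3))

    def test_hand_evaluated_barycentric_oracle(self):
        # cation shares 50/25/25 (Ca/Mg/NaK), anion 60/25/15 (HCO3/SO4/Cl)
        s = sample_from_meq(Ca=2.0, Mg=1.0, Na=1.0, HCO3=6.0, SO4=2.5, Cl=1.5)
        c = aq.piper_coordinates(aq.ion_percentages(s))
        nak, mg = 0.25, 0.25
        assert c.cation_xy == pytest.approx((nak + mg / 2, mg * math.sqrt(3) / 2))
        cl, so4 = 0.15, 0.25
        assert c.anion_xy == pytest.approx(
            (1.1 + cl + so4 / 2, so4 * math.sqrt(3) / 2)
        )
        p, q = 0.25, 0.40
        assert c.diamond_shares == pytest.approx((p, q))
        assert c.diamond_xy == pytest.approx(
            ((p + q + 1.1) / 2, _H * (1.1 + q - p))
        )

    def test_barycentric_triples_sum_to_one(self, six_well_panel):
        for s in six_well_panel:
            c = aq.piper_coordinates(aq.ion_percentages(s))
            assert sum(c.cation_bary) == pytest.approx(1.0)
            assert sum(c.anion_bary) == pytest.approx(1.0)
            assert 0 <= c.diamond_shares[0] <= 1
            assert 0 <= c.diamond_shares[1] <= 1


class TestFacies:
    @pytest.mark.parametrize(
        "meq, expected",
        [
            (dict(Ca=8.5, Na=1.5, HCO3=9, Cl=1), "Ca-HCO3"),
            (dict(Ca=7, Mg=1.5, Na=1.5, HCO3=5.5, SO4=3.5, Cl=1), "Ca-HCO3-SO4"),
            (dict(Na=7.5, Ca=1.5, Mg=1, Cl=8.5, HCO3=1.5), "Na-Cl"),
            (dict(Ca=5, Mg=5, HCO3=5, SO4=5), "Ca-Mg-HCO3-SO4"),
        ],
    )
    def test_threshold_rule(self, meq, expected):
        shares = aq.ion_percentages(sample_from_meq(**meq))
        assert aq.classify_facies(shares) == expected

    def test_tokens_ordered_by_descending_share(self):
        shares = aq.ion_percentages(
            sample_from_meq(Mg=6, Ca=4, SO4=7, HCO3=3)
        )
        assert aq.classify_facies(shares) == "Mg-Ca-SO4-HCO3"

    def test_uniform_scaling_invariance(self):
        meq = dict(Ca=4.9, Mg=1.2, Na=2.1, HCO3=5.0, SO4=2.2, Cl=0.9)
        s1 = aq.ion_percentages(sample_from_meq(**meq))
        s2 = aq.ion_percentages(
            sample_from_meq(**{k: 17.3 * v for k, v in meq.items()})
        )
        assert aq.classify_facies(s1) == aq.classify_facies(s2)

    def test_threshold_is_configurable(self):
        shares = aq.ion_percentages(sample_from_meq(Ca=7, Mg=3, HCO3=10))
        assert aq.classify_facies(shares) == "Ca-Mg-HCO3"
        assert aq.classify_facies(shares, threshold_pct=40.0) == "Ca-HCO3"


class TestFaciesDistribution:
    def test_published_split(self):
        labels = ["Ca-HCO3"] * 4 + ["Ca-HCO3-SO4"] * 2
        dist = aq.facies_distribution(labels)
        assert dist["Ca-HCO3"] == pytest.approx(66.67, abs=0.01)
        assert dist["Ca-HCO3-SO4"] == pytest.approx(33.33, abs=0.01)

    def test_single_label(self):
        assert aq.facies_distribution(["Na-Cl"]) == {"Na-Cl": 100.0}

    def test_three_distinct(self):
        dist = aq.facies_distribution(["A", "B", "C"])
        assert all(v == pytest.approx(100 / 3) for v in dist.values())

    def test_empty_rejected(self):
        with pytest.raises(aq.InputDataError):
            aq.facies_distribution([])


def test_plot_piper_renders(six_well_panel, tmp_path):
    coords = [aq.piper_coordinates(aq.ion_percentages(s)) for s in six_well_panel]
    ax = aq.piper.plot_piper(coords, labels=[s.well_id for s in six_well_panel])
    out = tmp_path / "piper.png"
    ax.figure.savefig(out)
    assert out.stat().st_size > 0
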