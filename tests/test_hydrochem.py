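"""Descriptive statistics, scalar classification rules, compliance, Pearson."""

import math

import numpy as np
import pytest

import aquagrade as aq


class TestSummaryStats:
    def test_single_sample_degenerates(self):
        stats = aq.summary_stats([aq.WellSample("w", {"TDS": 500.0})])
        row = stats.loc["TDS"]
        assert row["Min"] == row["Max"] == row["Mean"] == 500.0
        assert row["Std. Deviation"] == 0.0

    def test_two_values_with_sample_denominator(self):
        samples = [aq.WellSample("a", {"TH": 1.0}), aq.WellSample("b", {"TH": 3.0})]
        row = aq.summary_stats(samples).loc["TH"]
        assert row["Mean"] == pytest.approx(2.0)
        assert row["Std. Deviation"] == pytest.approx(math.sqrt(2))

    def test_published_table_layout(self, six_well_panel):
        stats = aq.summary_stats(six_well_panel)
        assert list(stats.columns) == ["Min", "Max", "Mean", "Std. Deviation"]
        assert ((stats["Min"] <= stats["Mean"]) & (stats["Mean"] <= stats["Max"])).all()

    def test_empty_panel_rejected(self):
        with pytest.raises(aq.InputDataError):
            aq.summary_stats([])


@pytest.mark.parametrize(
    "fn, value, expected",
    [
        (aq.classify_hardness, 10, "soft"),
        (aq.classify_hardness, 75, "soft"),
        (aq.classify_hardness, 100, "moderately hard"),
        (aq.classify_hardness, 200, "hard"),
        (aq.classify_hardness, 300, "hard"),
        (aq.classify_hardness, 437.92, "very hard"),
        (aq.classify_tds, 566.63, "fresh"),
        (aq.classify_tds, 1000, "fresh"),
        (aq.classify_tds, 5000, "brackish"),
        (aq.classify_tds, 50_000, "saline"),
        (aq.classify_tds, 2e6, "brine"),
        (aq.classify_ec, 915.75, "type I"),
        (aq.classify_ec, 1500, "type I"),
        (aq.classify_ec, 2000, "type II"),
        (aq.classify_ec, 3500, "type III"),
        (aq.classify_ph, 7.0, "neutral"),
        (aq.classify_ph, 6.9, "neutral"),
        (aq.classify_ph, 7.1, "neutral"),
        (aq.classify_ph, 5.0, "acidic"),
        (aq.classify_ph, 9.0, "alkaline"),
    ],
)
def test_scalar_classification_rules(fn, value, expected):
    assert fn(value) == expected


def test_classifications_are_monotone_step_functions():
    order = ["soft", "moderately hard", "hard", "very hard"]
    previous = 0
    for th in np.linspace(0, 700, 211):
        rank = order.index(aq.classify_hardness(float(th)))
        assert rank >= previous
        previous = rank


def test_ph_band_is_configurable():
    assert aq.classify_ph(7.15, band=0.1) == "alkaline"
    assert aq.classify_ph(7.15, band=0.2) == "neutral"


class TestCompliance:
    def test_tds_against_both_schemes(self):
        sample = aq.WellSample("w", {"TDS": 824.90})
        who = aq.compliance_flags(sample, aq.builtin_drinking_limits("WHO2011"))
        gb = aq.compliance_flags(sample, aq.builtin_drinking_limits("GB5749"))
        assert who["TDS"] == "exceeds"
        assert gb["TDS"] == "within"

    def test_ph_range_limit(self):
        limits = aq.builtin_drinking_limits("WHO2011")
        assert aq.compliance_flags(aq.WellSample("w", {"pH": 7.0}), limits)["pH"] == "within"
        assert aq.compliance_flags(aq.WellSample("w", {"pH": 9.0}), limits)["pH"] == "exceeds"
        assert aq.compliance_flags(aq.WellSample("w", {"pH": 6.0}), limits)["pH"] == "exceeds"

    def test_unlimited_indicators_are_skipped(self):
        sample = aq.WellSample("w", {"EC": 900.0, "K": 2.0})
        flags = aq.compliance_flags(sample, aq.builtin_drinking_limits("GB5749"))
        assert flags == {}


class TestPearson:
    def test_hand_computed_oracle(self):
        samples = [
            aq.WellSample("a", {"x": 0.0, "y": 0.0}),
            aq.WellSample("b", {"x": 1.0, "y": 1.0}),
            aq.WellSample("c", {"x": 2.0, "y": 4.0}),
        ]
        corr = aq.pearson_matrix(samples)
        assert corr.r.loc["x", "y"] == pytest.approx(6 / math.sqrt(39))

    def test_perfect_anticorrelation_and_unit_diagonal(self):
        samples = [
            aq.WellSample(str(i), {"x": float(i), "y": 10.0 - i}) for i in range(5)
        ]
        corr = aq.pearson_matrix(samples)
        assert corr.r.loc["x", "y"] == pytest.approx(-1.0)
        assert corr.r.loc["x", "x"] == 1.0
        assert np.allclose(corr.r.values, corr.r.values.T)

    def test_affine_rescaling_leaves_r_unchanged(self, six_well_panel):
        corr = aq.pearson_matrix(six_well_panel)
        rescaled = [
            aq.WellSample(s.well_id, {**s.values, "TDS": 3.0 * s.values["TDS"] + 7.0})
            for s in six_well_panel
        ]
        corr2 = aq.pearson_matrix(rescaled)
        assert corr2.r.loc["TDS", "TH"] == pytest.approx(corr.r.loc["TDS", "TH"])

    def test_zero_variance_column_flagged_undefined(self):
        samples = [
            aq.WellSample(str(i), {"x": float(i), "const": 5.0}) for i in range(4)
        ]
        corr = aq.pearson_matrix(samples)
        assert corr.undefined == ["const"]
        assert np.isnan(corr.r.loc["x", "const"])

    def test_too_few_samples_rejected(self):
        samples = [aq.WellSample("a", {"x": 1.0}), aq.WellSample("b", {"x": 2.0})]
        with pytest.raises(aq.InsufficientDataError):
            aq.pearson_matrix(samples)

    def test_significance_markers(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1.0, 10.0, size=30)
        samples = [
            aq.WellSample(str(i), {"x": float(v),
                                   "y": float(v + 0.01 * rng.uniform()),
                                   "z": float(rng.uniform())})
            for i, v in enumerate(x)
        ]
        corr = aq.pearson_matrix(samples)
        markers = corr.markers()
        assert markers.loc["x", "y"] == "**"
        assert corr.significance(0.01).loc["x", "y"]

    def test_strength_labels(self):
        assert aq.CorrelationMatrix.strength(0.9) == "strong"
        assert aq.CorrelationMatrix.strength(-0.6) == "moderate"
        assert aq.CorrelationMatrix.strength(0.2) == "weak"
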