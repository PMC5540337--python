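"""The appearance -> encounter -> passage entry-rate model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrisk.geometry import Circle, Ellipse, HoleMetrics, Measured, Rectangle
from netrisk.model import (
    EntryRiskModel,
    Hole,
    NoSolutionError,
    UnsupportedSplitError,
    appearance_rate,
    assess_net,
    encounter_probability,
    equivalent_diameter,
    hole_entry_rate,
    passage_probability,
    scale_risk,
    split_at_fa_boundaries,
    split_long_hole,
)
from netrisk.params import FunctionalArea, SpeciesParameters

FA = FunctionalArea


def rect_hole(fa, length, width, id="h"):
    return Hole.from_shape(id, fa, Rectangle(length_mm=length, width_mm=width))


class TestElementaryTerms:
    @pytest.mark.parametrize(
        "fa,rate", [(FA.FA1, 72.3), (FA.FA2_LOW, 9.5), (FA.FA2_HIGH, 1.5), (FA.FA3, 0.3)]
    )
    def test_appearance_rates(self, fa, rate, params):
        assert appearance_rate(fa, params) == rate

    def test_underlying_activity_ratio(self, params):
        # hourly cohort activity 14450:1900:300:60 is ~250:33:5:1 per unit area
        rates = params.appearances_per_mosquito_hour
        ratios = [rates[FA.FA1] / rates[FA.FA3], rates[FA.FA2_LOW] / rates[FA.FA3],
                  rates[FA.FA2_HIGH] / rates[FA.FA3]]
        assert ratios == pytest.approx([241.0, 31.7, 5.0], rel=0.01)

    def test_encounter_probability_square_300(self, params):
        m = HoleMetrics(perimeter=1200, area=90000, avg_width=300)
        assert encounter_probability(m, params) == pytest.approx(0.8208)

    def test_encounter_probability_fig9_tear(self, params):
        m = HoleMetrics(perimeter=740, area=21000, avg_width=70)
        assert encounter_probability(m, params) == pytest.approx(0.19566)

    def test_encounter_probability_zero_hole(self, params):
        assert encounter_probability(HoleMetrics(0, 0, 0), params) == 0.0

    def test_passage_zero_at_threshold(self, params):
        assert passage_probability(5.0, "side", params) == 0.0
        assert passage_probability(0.0, "roof", params) == 0.0

    def test_passage_roof_30mm(self, params):
        expected = 0.34 * math.log(30) - 0.55
        assert passage_probability(30, "roof", params) == pytest.approx(expected)
        assert expected == pytest.approx(0.6064, abs=1e-4)

    def test_passage_clamps_at_one_for_gaping_holes(self, params):
        assert 0.30 * math.log(307) - 0.52 > 1
        assert passage_probability(307, "side", params) == 1.0

    def test_zero_crossings_match_impassability_threshold(self, params):
        assert params.passage_roof.zero_crossing_mm == pytest.approx(5.04, abs=0.01)
        assert params.passage_side.zero_crossing_mm == pytest.approx(5.65, abs=0.01)


class TestHoleRate:
    def test_roof_square_rate(self, params):
        risk = hole_entry_rate(rect_hole(FA.FA1, 30, 30), params)
        assert risk.entries_per_hour == pytest.approx(0.4025, abs=2e-4)

    def test_fa2low_tear_rate(self, params):
        risk = hole_entry_rate(rect_hole(FA.FA2_LOW, 300, 70), params)
        assert risk.entries_per_hour == pytest.approx(1.4025, abs=2e-4)
        assert risk.entries_per_hour == pytest.approx(
            risk.appearances_per_hour * risk.encounter_prob * risk.passage_prob
        )

    def test_impassable_hole_rate_zero(self, params):
        assert hole_entry_rate(rect_hole(FA.FA1, 200, 5), params).entries_per_hour == 0.0


class TestNetAssessment:
    def test_typical_damage_scenario(self, fig9, params):
        res = assess_net(fig9, params)
        assert res.total_entries_per_hour == pytest.approx(6.30091, abs=1e-3)
        assert res.fraction_sides == pytest.approx(0.808, abs=0.002)

    def test_roof_only_damage(self, fig9_roof, params):
        res = assess_net(fig9_roof, params)
        assert res.total_entries_per_hour == pytest.approx(1.207, abs=1e-3)

    def test_equal_risk_round_holes(self, fig10, params):
        # the published scenario intentionally includes a 307 mm FA3 hole
        res = assess_net(fig10, params, normalize=False)
        by_fa = res.fa_totals
        assert by_fa[FA.FA1] == pytest.approx(0.2017, abs=1e-3)
        assert by_fa[FA.FA2_LOW] == pytest.approx(0.2049, abs=1e-3)
        assert by_fa[FA.FA2_HIGH] == pytest.approx(0.2024, abs=1e-3)
        assert by_fa[FA.FA3] == pytest.approx(0.2025, abs=1e-3)

    def test_empty_net(self, params):
        res = assess_net([], params)
        assert res.total_entries_per_hour == 0.0
        assert res.fraction_roof == 0.0
        assert sum(res.fraction_by_fa.values()) == 0.0

    def test_fractions_sum_to_one(self, fig9, params):
        res = assess_net(fig9, params)
        assert sum(res.fraction_by_fa.values()) == pytest.approx(1.0)

    def test_additivity_over_partitions(self, fig9, params):
        whole = assess_net(fig9, params).total_entries_per_hour
        parts = sum(
            assess_net([h], params).total_entries_per_hour for h in fig9
        )
        assert whole == pytest.approx(parts)

    def test_summary_mentions_total(self, fig9, params):
        text = EntryRiskModel(fig9, params).fit().summary()
        assert "6.30" in text and "TOTAL" in text


class TestScaling:
    def test_identity_and_linearity(self, fig9, params):
        res = assess_net(fig9, params)
        assert scale_risk(res, 1, 1).total_entries == pytest.approx(res.total_entries_per_hour)
        assert scale_risk(res, 2, 3).total_entries == pytest.approx(
            6 * res.total_entries_per_hour
        )

    def test_zero_total_stays_zero(self, params):
        res = assess_net([], params)
        assert scale_risk(res, 5, 8).total_entries == 0.0

    def test_negative_inputs_rejected(self, fig9, params):
        with pytest.raises(ValueError):
            scale_risk(assess_net(fig9, params), -1, 1)


class TestSplitting:
    def test_400mm_rectangle_splits_in_two(self, params):
        parts = split_long_hole(rect_hole(FA.FA2_LOW, 400, 50), params=params)
        assert len(parts) == 2
        assert all(p.shape.length_mm == 200 for p in parts)
        assert all(p.shape.width_mm == 50 for p in parts)

    def test_boundary_rectangle_unchanged(self, params):
        hole = rect_hole(FA.FA2_LOW, 300, 50)
        assert split_long_hole(hole, params=params) == [hole]

    def test_900mm_split_preserves_area(self, params):
        parts = split_long_hole(rect_hole(FA.FA3, 900, 20), params=params)
        assert len(parts) == 3
        assert sum(p.metrics.area for p in parts) == pytest.approx(900 * 20)
        # each fragment carries its own full perimeter
        assert all(p.metrics.perimeter == pytest.approx(2 * (300 + 20)) for p in parts)

    def test_measured_with_length_splits(self, params):
        shape = Measured(perimeter_mm=900, area_mm2=17500, avg_width_mm=50, length_mm=350)
        parts = split_long_hole(Hole.from_shape("m", FA.FA3, shape, params), params=params)
        assert len(parts) == 2
        assert sum(p.metrics.area for p in parts) == pytest.approx(17500)

    def test_oversize_ellipse_unsupported(self, params):
        hole = Hole.from_shape("e", FA.FA3, Ellipse(major_mm=400, minor_mm=30), params)
        with pytest.raises(UnsupportedSplitError):
            split_long_hole(hole, params=params)

    def test_strict_model_rejects_oversize_circle(self, params):
        big = Hole.from_shape("c", FA.FA3, Circle(diameter_mm=307), params)
        with pytest.raises(UnsupportedSplitError):
            EntryRiskModel([big], params, strict=True)
        with pytest.warns(UserWarning):
            EntryRiskModel([big], params)  # default keeps it, warning

    def test_fa_boundary_apportioning(self, params):
        # a 700 mm tall tear starting at the hem crosses both boundaries
        parts = split_at_fa_boundaries("t", length_mm=700, width_mm=40,
                                       bottom_height_mm=0, params=params)
        assert [p.fa for p in parts] == [FA.FA2_LOW, FA.FA2_HIGH, FA.FA3]
        assert sum(p.metrics.area for p in parts) == pytest.approx(700 * 40)


class TestEquivalentDiameter:
    def test_self_consistency(self, params):
        for fa in FA:
            rate = hole_entry_rate(
                Hole.from_shape("c", fa, Circle(diameter_mm=40), params), params
            ).entries_per_hour
            assert equivalent_diameter(rate, fa, params) == pytest.approx(40, abs=0.01)

    def test_published_equivalents(self, params):
        ref = hole_entry_rate(
            Hole.from_shape("ref", FA.FA1, Circle(diameter_mm=25), params), params
        ).entries_per_hour
        assert round(equivalent_diameter(ref, FA.FA2_LOW, params) / 10, 1) == 6.3
        assert round(equivalent_diameter(ref, FA.FA2_HIGH, params) / 10, 1) == 13.9
        # the FA3 solution sits under the passage clamp
        assert 300 < equivalent_diameter(ref, FA.FA3, params) < 310

    def test_unattainable_target(self, params):
        with pytest.raises(NoSolutionError):
            equivalent_diameter(1000.0, FA.FA3, params, bound=500)
        with pytest.raises(NoSolutionError):
            equivalent_diameter(0.0, FA.FA1, params)


class TestModelProperties:
    @given(
        length=st.floats(min_value=100, max_value=290),
        width=st.floats(min_value=5.5, max_value=100),
        bump=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=40, deadline=None)
    def test_rate_monotone_in_width_and_length(self, length, width, bump, params):
        fa = FA.FA2_LOW
        base = hole_entry_rate(rect_hole(fa, length, width), params).entries_per_hour
        wider = hole_entry_rate(rect_hole(fa, length, width + bump), params)
        longer = hole_entry_rate(rect_hole(fa, length + bump, width), params)
        assert wider.entries_per_hour >= base - 1e-12
        assert longer.entries_per_hour >= base - 1e-12

    @given(width=st.floats(min_value=6, max_value=300),
           length=st.floats(min_value=6, max_value=300))
    @settings(max_examples=40, deadline=None)
    def test_fa_risk_ordering(self, width, length, params):
        length, width = max(length, width), min(length, width)
        rates = [
            hole_entry_rate(rect_hole(fa, length, width), params).entries_per_hour
            for fa in (FA.FA1, FA.FA2_LOW, FA.FA2_HIGH, FA.FA3)
        ]
        assert rates[0] > rates[1] > rates[2] > rates[3]

    @given(width=st.floats(min_value=0, max_value=1000))
    @settings(max_examples=60, deadline=None)
    def test_probabilities_always_clamped(self, width, params):
        for orientation in ("roof", "side"):
            assert 0.0 <= passage_probability(width, orientation, params) <= 1.0

    @given(width=st.floats(min_value=6, max_value=90))
    @settings(max_examples=40, deadline=None)
    def test_roof_passage_premium(self, width, params):
        roof = passage_probability(width, "roof", params)
        side = passage_probability(width, "side", params)
        assert roof > side


class TestParameterConfig:
    def test_yaml_override_roundtrip(self, tmp_path):
        cfg = tmp_path / "species.yaml"
        cfg.write_text(
            "encounter_coefficient: 1.0e-5\n"
            "passage_side: {slope: 0.25, intercept: -0.45}\n"
        )
        p = SpeciesParameters.from_file(cfg)
        assert p.encounter_coefficient == 1e-5
        assert p.passage_side.slope == 0.25
        # untouched fields keep the An. gambiae defaults
        assert p.appearances_per_mosquito_hour[FA.FA1] == 72.3

    def test_parameter_hash_changes_with_values(self, params, tmp_path):
        cfg = tmp_path / "p.json"
        cfg.write_text('{"encounter_coefficient": 8e-6}')
        assert SpeciesParameters.from_file(cfg).parameter_hash() != params.parameter_hash()
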