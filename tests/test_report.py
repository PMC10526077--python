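import pytest
from hypothesis import given, settings, strategies as st

from radkin.model import MediumSpec, ReactionPathway
from radkin.report import (
    PathwayRate,
    ScenarioResult,
    branching_ratios,
    compare_to_references,
    overall_rate,
    render_json,
    render_markdown,
    weight_rate,
)


class TestWeightRate:
    @pytest.mark.parametrize(
        "k_app,f,expected",
        [
            (7.80e4, 0.012, 9.36e2),
            (6.60e2, 0.918, 6.06e2),
            (5.0e9, 0.0, 0.0),
        ],
    )
    def test_population_weighting(self, k_app, f, expected):
        assert weight_rate(k_app, f) == pytest.approx(expected, rel=1e-3)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            weight_rate(1.0, 1.2)
        with pytest.raises(ValueError):
            weight_rate(1.0, -0.1)


class TestOverallRate:
    def test_electron_transfer_dominated_sum(self):
        assert overall_rate([1.68e2, 1.19, 9.36e2, 2.28e7]) == pytest.approx(2.28e7, rel=1e-3)

    def test_lipid_medium_sum(self):
        assert overall_rate([1.80e6, 2.90e5, 3.40e-2]) == pytest.approx(2.09e6, rel=1e-3)

    def test_single_element_identity_and_empty_rejected(self):
        assert overall_rate([42.0]) == 42.0
        with pytest.raises(ValueError):
            overall_rate([])


class TestBranchingRatios:
    def test_hydrogen_abstraction_dominates_catechol(self):
        rates = [606.0, 77.1, 0.023, 1.89e8, 19.7, 7.95e7]
        gamma = branching_ratios(rates)
        assert round(gamma[3]) == 70
        assert round(gamma[5]) == 30

    def test_electron_transfer_exclusive(self):
        gamma = branching_ratios([168.0, 1.19, 936.0, 2.28e7])
        assert round(gamma[3]) == 100

    def test_uniform_rates_split_evenly(self):
        gamma = branching_ratios([5.0] * 4)
        assert all(g == pytest.approx(25.0, rel=1e-12) for g in gamma)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            branching_ratios([0.0, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(
        rates=st.lists(st.floats(1e-6, 1e12), min_size=1, max_size=8),
        scale=st.floats(1e-3, 1e3),
    )
    def test_sum_to_hundred_and_scale_invariant(self, rates, scale):
        gamma = branching_ratios(rates)
        assert sum(gamma) == pytest.approx(100.0, abs=1e-9)
        rescaled = branching_ratios([r * scale for r in rates])
        for a, b in zip(gamma, rescaled):
            assert a == pytest.approx(b, rel=1e-9)


class TestReferenceComparison:
    def test_water_ranking_above_trolox(self):
        table = compare_to_references(2.68e8, "water")
        names = list(table["antioxidant"])
        assert names.index("(computed)") < names.index("Trolox")

    def test_lipid_ranking_between_trolox_and_bht(self):
        table = compare_to_references(4.10e4, "pentyl-ethanoate")
        names = list(table["antioxidant"])
        assert names.index("Trolox") < names.index("(computed)") < names.index("BHT")

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError, match="no reference constants"):
            compare_to_references(1e5, "olive oil")


def _tiny_result():
    medium = MediumSpec(name="water", aqueous=True, pH=7.4)
    p1 = ReactionPathway("cpd", "anion", "HAT", site="12OH", dG_activation=2.0, kappa=1.2)
    p2 = ReactionPathway("cpd", "anion", "RAF", site="C8", dG_activation=14.2)
    rates = [
        PathwayRate(p1, 1.2, 2.0, 2.5e11, 2.3e9, 2.3e9, 0.082),
        PathwayRate(p2, 1.0, 14.2, 2.4e2, 2.3e9, 2.4e2, 0.082),
    ]
    return ScenarioResult("cpd", medium, rates)


def test_scenario_result_invariants():
    res = _tiny_result()
    assert res.k_overall == pytest.approx(sum(pr.k_weighted for pr in res.pathway_rates), rel=1e-12)
    assert sum(pr.branching_pct for pr in res.pathway_rates) == pytest.approx(100.0, abs=1e-9)
    for pr in res.pathway_rates:
        assert pr.k_weighted == pytest.approx(pr.k_app * pr.mole_fraction, rel=1e-12)


def test_markdown_render_carries_table_footnotes():
    md = render_markdown([_tiny_result()])
    assert "^a^ mole fraction" in md
    assert "k_f = f·k_app" in md
    assert "k_overall" in md


def test_json_render_is_deterministic():
    a = render_json([_tiny_result()])
    b = render_json([_tiny_result()])
    assert a == b and '"k_overall"' in a
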