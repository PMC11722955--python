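import pytest

from dietshift import (
    DietBasket,
    DietShiftError,
    FoodItem,
    PlantSource,
    ReplacementMix,
    ScenarioSpec,
    ValidationError,
    land_use_final,
    land_use_initial,
    land_use_replaced,
    protein_units,
    run_scenario,
    scenario_sweep,
    weighted_plant_intensity,
)


def single_source_mix(intensity: float) -> ReplacementMix:
    return ReplacementMix(((PlantSource("plant", intensity), 1.0),))


class TestProteinUnits:
    @pytest.mark.parametrize(
        "consumption,protein,expected",
        [
            (22.21, 17.1, 37.98),  # poultry: 100% of units are replaced at rate 1
            (599.32, 3.3, 197.78),  # milk
            (0.0, 17.1, 0.0),
        ],
    )
    def test_examples(self, consumption, protein, expected):
        assert protein_units(consumption, protein) == pytest.approx(expected, abs=5e-3)

    def test_rejects_negative_inputs(self):
        with pytest.raises(DietShiftError):
            protein_units(-1.0, 10.0)
        with pytest.raises(DietShiftError):
            protein_units(1.0, -10.0)


class TestPerFoodLandUse:
    def test_initial_land_use_full_precision(self, basket):
        poultry = basket["Poultry"]
        assert land_use_initial(poultry) == pytest.approx(
            22.21 * 17.1 / 10 * 7.06, rel=1e-12
        )
        # published cell rounds intermediates: 267.96 vs full-precision 268.13
        assert land_use_initial(poultry) == pytest.approx(267.96, rel=5e-3)
        assert land_use_initial(basket["Beef"]) == pytest.approx(1528.39, rel=5e-3)

    def test_zero_consumption_uses_no_land(self):
        assert land_use_initial(FoodItem("x", 0.0, 18.5, 163.6)) == 0.0

    def test_weighted_intensity_is_convex_combination(self, mix):
        assert weighted_plant_intensity(mix) == pytest.approx(3.144, abs=1e-12)
        assert weighted_plant_intensity(single_source_mix(5.18)) == 5.18
        same = ReplacementMix.from_triples([("a", 0.7, 4.0), ("b", 0.3, 4.0)])
        assert weighted_plant_intensity(same) == pytest.approx(4.0, rel=1e-12)

    def test_replaced_land_examples(self, basket, mix):
        milk = basket["Milk"]
        full = land_use_replaced(milk, ScenarioSpec(1.0, mix))
        assert full == pytest.approx(621.81, rel=5e-3)
        partial = land_use_replaced(milk, ScenarioSpec(0.33, mix))
        assert partial == pytest.approx(205.20, rel=5e-3)
        assert land_use_replaced(milk, ScenarioSpec(0.0, mix)) == 0.0

    def test_final_land_examples(self, basket, mix):
        pig = basket["Pig meat"]
        assert land_use_final(pig, ScenarioSpec(0.5, mix)) == pytest.approx(
            371.69, rel=5e-3
        )
        beef = basket["Beef"]
        assert land_use_final(beef, ScenarioSpec(1.0, mix)) == pytest.approx(
            1499.02, rel=5e-3
        )
        assert land_use_final(pig, ScenarioSpec(0.0, mix)) == land_use_initial(pig)

    def test_rate_outside_unit_interval_rejected(self, mix):
        with pytest.raises(DietShiftError):
            ScenarioSpec(1.5, mix)
        with pytest.raises(DietShiftError):
            ScenarioSpec(-0.1, mix)


class TestRunScenario:
    def test_totals_are_column_sums_and_conservation_exact(self, basket, mix):
        result = run_scenario(basket, ScenarioSpec(0.33, mix))
        assert result.total_initial == sum(r.lu_initial for r in result.rows)
        assert result.total_replaced == sum(r.lu_replaced for r in result.rows)
        for row in result.rows:
            assert row.lu_final == row.lu_initial - row.lu_replaced  # exact
        assert result.total_final == result.total_initial - result.total_replaced
        assert result.per_capita_saving == result.total_replaced

    def test_zero_rate_changes_nothing(self, basket, mix):
        result = run_scenario(basket, ScenarioSpec(0.0, mix))
        assert result.total_final == result.total_initial
        assert result.per_capita_saving == 0.0

    def test_full_replacement_total(self, basket, mix):
        result = run_scenario(basket, ScenarioSpec(1.0, mix))
        assert result.total_final == pytest.approx(7450.14, rel=1e-3)

    def test_break_even_item_frees_no_net_land(self):
        """When the mix's weighted intensity equals an item's animal
        intensity, the animal land freed (rate x initial) exactly cancels
        the plant land claimed, at any rate."""
        mix = single_source_mix(4.0)
        basket = DietBasket((FoodItem("even", 10.0, 10.0, 4.0),))
        for rate in (0.25, 1.0):
            result = run_scenario(basket, ScenarioSpec(rate, mix))
            row = result.rows[0]
            net = rate * row.lu_initial - row.lu_replaced
            assert net == pytest.approx(0.0, abs=1e-12)
            assert not result.warnings

    def test_costlier_mix_flagged_not_clipped(self):
        """A mix more land-hungry than the animal source claims more land
        than the food used in the first place; the result is reported as-is
        with a warning record, never clipped."""
        mix = single_source_mix(5.0)
        basket = DietBasket((FoodItem("fishlike", 10.0, 10.0, 3.69),))
        result = run_scenario(basket, ScenarioSpec(1.0, mix))
        row = result.rows[0]
        assert row.lu_replaced > row.lu_initial
        assert result.total_final < 0  # not clipped at zero
        assert len(result.warnings) == 1 and "fishlike" in result.warnings[0]


class TestSweep:
    def test_published_rate_sequence(self, basket, mix):
        results = scenario_sweep(basket, (0.33, 0.5, 1.0), mix)
        finals = [r.total_final for r in results]
        assert finals == pytest.approx([8108.35, 7941.34, 7450.14], rel=1e-3)
        assert len({r.total_initial for r in results}) == 1

    def test_repeated_rate_gives_identical_results(self, basket, mix):
        a, b = scenario_sweep(basket, (0.5, 0.5), mix)
        assert a == b

    def test_replaced_land_linear_in_rate(self, basket, mix):
        half, full = scenario_sweep(basket, (0.5, 1.0), mix)
        assert full.total_replaced == pytest.approx(2 * half.total_replaced, rel=1e-12)
        for r_half, r_full in zip(half.rows, full.rows):
            assert r_full.lu_replaced == pytest.approx(2 * r_half.lu_replaced, rel=1e-12)

    def test_final_total_strictly_decreasing_in_rate(self, basket, mix):
        # mix intensity 3.144 is below every fixture animal intensity
        finals = [r.total_final for r in scenario_sweep(basket, (0.0, 0.2, 0.6, 1.0), mix)]
        assert all(a > b for a, b in zip(finals, finals[1:]))

    def test_empty_rate_list_rejected(self, basket, mix):
        with pytest.raises(ValidationError):
            scenario_sweep(basket, (), mix)
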