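"""Mixture self-classification, adjustment bounds and iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbdkit.core import ClassificationError, Formulation, HazardEntry, Ingredient
from sbdkit.fixtures import random_formulation
from sbdkit.screening import (
    CompositionEdit,
    classify_mixture,
    iterate_screening,
    suggest_adjustments,
)


def water(fraction):
    return Ingredient(id="water", name="water", mass_fraction=fraction)


class TestThresholdRules:
    def test_irritant_at_gcl_classifies(self, registry, water_mix):
        c = classify_mixture(water_mix(12.0), registry)
        assert c.has("skin_irritation", "2")
        driver = c.assigned[0].driver
        assert driver.method == "threshold"
        assert [t.id for t in driver.triggering_ingredients] == ["irritant"]

    def test_boundary_is_inclusive(self, registry, water_mix):
        assert classify_mixture(water_mix(10.0), registry).has("skin_irritation")
        assert not classify_mixture(water_mix(9.999), registry).has("skin_irritation")

    def test_below_cutoff_ignored(self, registry, water_mix):
        c = classify_mixture(water_mix(0.5), registry)
        assert not c.assigned
        # and the ingredient is not even taken into account
        ev = next(e for e in c.evaluations if e.hazard_class == "skin_irritation")
        assert not ev.relevant

    def test_between_cutoff_and_gcl_counted_but_not_triggering(self, registry, water_mix):
        c = classify_mixture(water_mix(5.0), registry)
        ev = next(e for e in c.evaluations if e.hazard_class == "skin_irritation")
        assert [t.id for t in ev.relevant] == ["irritant"] and not ev.triggered

    def test_two_irritants_sum_across_ingredients(self, registry, skin_irritant):
        f = Formulation(
            id="pair",
            ingredients=(skin_irritant(6.0, "a"), skin_irritant(6.0, "b"), water(88.0)),
        )
        assert classify_mixture(f, registry).has("skin_irritation")

    def test_pure_water_unclassified(self, registry):
        c = classify_mixture(Formulation(id="w", ingredients=(water(100.0),)), registry)
        assert c.assigned == () and (c.count_H, c.count_ENV) == (0, 0)

    def test_range_valued_fraction_uses_upper_bound(self, registry, skin_irritant):
        ing = skin_irritant(5.0).with_fraction((8.0, 12.0))
        f = Formulation(id="r", ingredients=(ing, water(88.0)))
        assert classify_mixture(f, registry).has("skin_irritation")


class TestAdditivity:
    def test_single_ingredient_ate_banding(self, registry):
        ing = Ingredient(
            id="tox",
            mass_fraction=50.0,
            hazards=(HazardEntry(hazard_class="acute_toxicity_oral", category="3"),),
            ate={"oral": 300.0},
        )
        c = classify_mixture(Formulation(id="f", ingredients=(ing, water(50.0))), registry)
        a = next(x for x in c.assigned if x.entry.hazard_class == "acute_toxicity_oral")
        # ATE_mix = 100 / (50/300) = 600 -> category 4 (300 < ATE <= 2000)
        assert a.entry.category == "4"
        assert a.driver.value == pytest.approx(600.0)

    def test_category_conversion_value_used_without_ate(self, registry):
        ing = Ingredient(
            id="tox",
            mass_fraction=50.0,
            hazards=(HazardEntry(hazard_class="acute_toxicity_oral", category="4"),),
        )
        c = classify_mixture(Formulation(id="f", ingredients=(ing, water(50.0))), registry)
        # converted ATE 500 -> ATE_mix 1000 -> still category 4
        assert c.has("acute_toxicity_oral", "4")

    def test_dilute_component_excluded(self, registry):
        ing = Ingredient(
            id="tox",
            mass_fraction=0.5,
            hazards=(HazardEntry(hazard_class="acute_toxicity_oral", category="1"),),
            ate={"oral": 1.0},
        )
        c = classify_mixture(Formulation(id="f", ingredients=(ing, water(99.5)),), registry)
        assert not c.assigned


class TestSummation:
    def make(self, fraction, category="2", m=1.0):
        ing = Ingredient(
            id="aq",
            mass_fraction=fraction,
            hazards=(HazardEntry(hazard_class="aquatic_chronic", category=category),),
            m_factor_chronic=m,
        )
        return Formulation(id="f", ingredients=(ing, water(min(100 - fraction, 60.0))))

    def test_chronic2_at_threshold(self, registry):
        assert classify_mixture(self.make(25.0), registry).has("aquatic_chronic", "2")
        assert not classify_mixture(self.make(24.99), registry).assigned

    def test_m_factor_scales_the_sum(self, registry):
        # 3% of an M=10 chronic-1 component: 30 >= 25 -> Chronic 1
        c = classify_mixture(self.make(3.0, category="1", m=10.0), registry)
        assert c.has("aquatic_chronic", "1")

    def test_category_cascade_assigns_most_severe_only(self, registry):
        c = classify_mixture(self.make(30.0, category="1"), registry)
        cats = [a.entry.category for a in c.assigned if a.entry.hazard_class == "aquatic_chronic"]
        assert cats == ["1"]


class TestClassificationContract:
    def test_missing_rule_is_an_explicit_error(self, registry):
        ing = Ingredient(
            id="x",
            mass_fraction=50.0,
            hazards=(HazardEntry(hazard_class="carcinogenicity", category="1A"),),
        )
        with pytest.raises(ClassificationError, match="carcinogenicity"):
            classify_mixture(Formulation(id="f", ingredients=(ing,)), registry)

    def test_all_unknown_formulation_flagged(self, registry):
        ing = Ingredient(
            id="x",
            mass_fraction=50.0,
            hazards=(HazardEntry(hazard_class="eye_irritation", category="2"),),
            sds_available=False,
        )
        c = classify_mixture(Formulation(id="f", ingredients=(ing,)), registry)
        assert c.not_classifiable and not c.assigned

    def test_large_unknown_fraction_warns_without_hazard(self, registry, skin_irritant):
        mystery = Ingredient(id="m", mass_fraction=15.0, sds_available=False)
        f = Formulation(id="f", ingredients=(skin_irritant(12.0), mystery, water(73.0)))
        c = classify_mixture(f, registry)
        assert c.unknown_fraction == pytest.approx(15.0)
        assert any("unknown" in w for w in c.warnings)
        assert c.hazard_count == 1

    def test_ingredient_order_irrelevant(self, registry, bundle):
        f = bundle.formulations["IF"]
        reordered = Formulation(
            id=f.id, label=f.label, ingredients=tuple(reversed(f.ingredients))
        )
        a = classify_mixture(f, registry)
        b = classify_mixture(reordered, registry)
        assert [x.entry for x in a.assigned] == [x.entry for x in b.assigned]


class TestAdjustmentSuggestions:
    def test_reference_case_bounds(self, registry, bundle):
        suggestions = suggest_adjustments(bundle.formulations["IF"], registry)
        by_bound = {s.bound: s for s in suggestions if s.ingredient_id == "ingredient_2"}
        assert sorted(by_bound, reverse=True) == [25.0, 10.0, 1.0]
        assert "aquatic_chronic" in by_bound[25.0].hazards_removed
        assert "eye_irritation" in by_bound[10.0].hazards_removed
        assert "eye_irritation" not in by_bound[25.0].hazards_removed
        assert by_bound[1.0].hazards_remaining == ()

    def test_bounds_nest_cumulatively(self, registry, bundle):
        suggestions = suggest_adjustments(bundle.formulations["IF"], registry)
        ordered = sorted(
            (s for s in suggestions if s.ingredient_id == "ingredient_2"),
            key=lambda s: -s.bound,
        )
        for earlier, later in zip(ordered, ordered[1:]):
            assert set(earlier.hazards_removed) <= set(later.hazards_removed)

    def test_no_hazards_no_suggestions(self, registry):
        f = Formulation(id="w", ingredients=(water(100.0),))
        assert suggest_adjustments(f, registry) == []

    def test_joint_drivers_flagged_and_verified(self, registry, skin_irritant):
        f = Formulation(
            id="pair",
            ingredients=(skin_irritant(6.0, "a"), skin_irritant(6.0, "b"), water(88.0)),
        )
        suggestions = suggest_adjustments(f, registry)
        assert {s.ingredient_id for s in suggestions} == {"a", "b"}
        s = next(x for x in suggestions if x.ingredient_id == "a")
        assert s.joint and s.bound == pytest.approx(4.0)
        below = classify_mixture(f.set_fraction("a", s.bound - 0.01), registry)
        assert not below.has("skin_irritation")

    @pytest.mark.parametrize("grid_step", [0.01])
    def test_analytic_bounds_match_grid_scan(self, registry, bundle, grid_step):
        """Brute-force oracle: re-classify on a fine concentration grid and
        locate each hazard's disappearance; must equal the analytic bound."""
        f = bundle.formulations["IF"]
        suggestions = [
            s for s in suggest_adjustments(f, registry) if s.ingredient_id == "ingredient_2"
        ]
        removal_bound = {}
        for s in suggestions:
            for cls in s.hazards_removed:
                removal_bound.setdefault(cls, s.bound)
        grid = np.arange(0.0, 41.0, grid_step)
        assigned_sets = [
            classify_mixture(f.set_fraction("ingredient_2", x), registry).assigned_classes
            for x in grid
        ]
        for cls, bound in removal_bound.items():
            present = np.array([cls in s for s in assigned_sets])
            first_present = grid[present.argmax()]
            assert present.any()
            assert first_present == pytest.approx(bound, abs=grid_step / 2)
            # below the bound the hazard never occurs, above it persists
            assert not present[grid < bound - 1e-9].any()
            assert present[grid >= bound].all()


class TestIteration:
    def test_reference_trajectory_shrinks(self, registry, bundle):
        IF = bundle.formulations["IF"]
        edits = [
            CompositionEdit(
                label="AF1",
                set_fractions={"ingredient_2": 0.70, "water": 91.0, "ingredient_1": (5.0, 10.0)},
                new_id="AF1",
            ),
            CompositionEdit(
                label="AF2",
                set_fractions={"ingredient_2": 0.01, "water": 99.09, "ingredient_1": 0.70},
                add=(Ingredient(id="ingredient_3", mass_fraction=0.20),),
                new_id="AF2",
            ),
        ]
        trajectory = iterate_screening(IF, edits, registry)
        sizes = [len(t.classification.assigned) for t in trajectory]
        assert [t.formulation_id for t in trajectory] == ["IF", "AF1", "AF2"]
        assert sizes[0] == 4 and sizes[1] == 0 and sizes[2] == 0
        assert len(trajectory[1].hazards_removed) == 4

    def test_empty_edit_list(self, registry, bundle):
        trajectory = iterate_screening(bundle.formulations["AF2"], [], registry)
        assert len(trajectory) == 1

    def test_raising_fraction_brings_hazards_back(self, registry, bundle):
        AF1 = bundle.formulations["AF1"]
        edits = [CompositionEdit(set_fractions={"ingredient_2": 30.0, "water": 60.0})]
        trajectory = iterate_screening(AF1, edits, registry)
        assert trajectory[1].hazards_added

    def test_invalid_edit_names_the_iteration(self, registry, bundle):
        edits = [CompositionEdit(label="bad", set_fractions={"water": 150.0})]
        with pytest.raises(ClassificationError, match="iteration 1"):
            iterate_screening(bundle.formulations["IF"], edits, registry)


class TestMonotonicityProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 6),
           density=st.floats(0.0, 1.0), bump=st.floats(0.1, 20.0))
    def test_increasing_a_hazardous_fraction_never_removes_hazards(
        self, registry, seed, n, density, bump
    ):
        f = random_formulation(n, density, seed)
        before = classify_mixture(f, registry)
        hazardous = [i for i in f.ingredients if i.hazards]
        if not hazardous:
            return
        target = hazardous[seed % len(hazardous)]
        new = min(target.mass_fraction.upper + bump, 100.0)
        slack = 100.0 - sum(
            i.mass_fraction.nominal for i in f.ingredients if i.id != target.id
        )
        bumped = f.set_fraction(target.id, min(new, max(slack, 0.0)))
        if bumped.ingredient(target.id).mass_fraction.upper < target.mass_fraction.upper:
            return
        after = classify_mixture(bumped, registry)
        assert before.assigned_classes <= after.assigned_classes

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 6), density=st.floats(0.0, 1.0),
           shrink=st.floats(0.01, 0.99))
    def test_dilution_never_adds_hazards(self, registry, seed, n, density, shrink):
        """Scaling every fraction down (adding a non-hazardous diluent) can
        only remove hazards."""
        f = random_formulation(n, density, seed)
        before = classify_mixture(f, registry)
        diluted = f
        for ing in f.ingredients:
            diluted = diluted.set_fraction(
                ing.id,
                (ing.mass_fraction.lower * shrink, ing.mass_fraction.upper * shrink),
            )
        after = classify_mixture(diluted, registry)
        assert after.assigned_classes <= before.assigned_classes

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6), density=st.floats(0.2, 1.0))
    def test_counts_and_determinism(self, registry, seed, n, density):
        f = random_formulation(n, density, seed)
        a = classify_mixture(f, registry)
        b = classify_mixture(f, registry)
        assert a == b
        assert a.count_H + a.count_ENV == len(a.assigned)
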