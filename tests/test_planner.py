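"""Meal-plan composer: slot calorie allocation, greedy composition against a
brute-force oracle, day-level compliance, substitution, and rendering."""

import itertools
import json

import pytest

from nutrikiosk.energy import MacroDistribution
from nutrikiosk.food_db import FoodGroup, init_db
from nutrikiosk.planner import (
    SLOTS,
    PlanConstraints,
    allocate_meal_calories,
    candidate_order,
    check_compliance,
    compose_meal,
    compose_plan,
    plan_from_json,
    render_plan,
    substitute_food,
)
from tests.test_food_db import item


def constraints(kcal=2000.0, **overrides):
    return PlanConstraints(
        daily_kcal_target=kcal, macro=MacroDistribution(50, 20, 30), **overrides
    )


class TestAllocation:
    @pytest.mark.parametrize(
        "daily,expected",
        [
            (2000, (500, 200, 600, 200, 500)),
            (1200, (300, 120, 360, 120, 300)),
        ],
    )
    def test_fixed_fractions(self, daily, expected):
        got = allocate_meal_calories(daily)
        assert tuple(got[s] for s in SLOTS) == expected

    @pytest.mark.parametrize("daily", [1200, 1333, 1999.4, 2477, 2800])
    def test_conservation(self, daily):
        got = allocate_meal_calories(daily)
        assert sum(got.values()) == int(round(daily))


class TestComposeMeal:
    def test_hand_simulated_greedy(self):
        """Exact replay of the greedy rule on a 3-food fixture.

        Order is V (GI 10), F (GI 40), C (unsuitable, last). V is added in
        half servings to its 3-serving cap (150 kcal), then F twice
        (150 -> 180 -> 210); 210 is inside [190, 210], so the fill stops.
        """
        foods = [
            item("V", kcal=50, cho=5, protein=2, fat=2.4, fiber=2, gi=10.0),
            item("F", group=FoodGroup.FRUIT, kcal=60, cho=15, protein=0, fat=0, gi=40.0),
            item("C", group=FoodGroup.CEREAL_TUBER, kcal=100, cho=20, protein=2, fat=0.9,
                 gi=70.0, suitable=False),
        ]
        slot = compose_meal(foods, 200.0, 60.0, constraints())
        assert slot.items == [("V", 3.0), ("F", 1.0)]
        assert slot.kcal == pytest.approx(210.0)
        assert slot.compliant

    def test_empty_candidates_non_compliant(self):
        slot = compose_meal([], 300.0, 60.0, constraints())
        assert not slot.compliant and slot.items == []

    def test_cho_cap_infeasibility_reason(self):
        # every half serving already busts the 10 g cap, kcal would still fit
        foods = [item("sugar", group=FoodGroup.SUGAR_SWEET, kcal=120, cho=30, gi=65.0)]
        slot = compose_meal(foods, 300.0, 10.0, constraints())
        assert not slot.compliant
        assert "cho_cap" in slot.reasons

    def test_candidate_order_contract(self):
        foods = [
            item("gi_none", gi=None, fiber=9),
            item("hi_fiber", gi=20.0, fiber=5),
            item("lo_fiber", gi=20.0, fiber=1),
            item("unsuitable", gi=5.0, suitable=False),
        ]
        assert [f.food_id for f in candidate_order(foods)] == [
            "hi_fiber", "lo_fiber", "gi_none", "unsuitable"
        ]


def brute_force_best(foods, target, cap, tol, gran=0.5, max_serv=3.0):
    """Exhaustive serving-combination search (the composer's oracle):
    is any combination within the kcal window and under the CHO cap?"""
    steps = [x * gran for x in range(int(max_serv / gran) + 1)]
    lower, upper = target * (1 - tol), target * (1 + tol)
    for combo in itertools.product(steps, repeat=len(foods)):
        kcal = sum(s * f.kcal for s, f in zip(combo, foods))
        cho = sum(s * f.cho_g for s, f in zip(combo, foods))
        if lower - 1e-9 <= kcal <= upper + 1e-9 and cho <= cap + 1e-9:
            return True
    return False


class TestGreedyOracle:
    @pytest.mark.parametrize("target,cap", [(150, 60), (300, 60), (500, 60), (250, 25)])
    def test_compliant_whenever_oracle_finds_solution(self, food_items, target, cap):
        """On small sub-databases, the greedy composer succeeds whenever
        exhaustive search proves a compliant combination exists."""
        cons = constraints()
        for start in range(0, 42, 7):
            foods = food_items[start : start + 6]
            slot = compose_meal(foods, float(target), float(cap), cons)
            feasible = brute_force_best(foods, target, cap, cons.kcal_tolerance)
            if feasible:
                assert slot.compliant, (
                    f"oracle found a combination for foods[{start}:{start+6}] "
                    f"target {target} but greedy flagged {slot.reasons}"
                )
            else:
                assert not slot.compliant


class TestComposePlan:
    def test_default_fixture_2000_kcal_compliant(self, db):
        plan = compose_plan(db, constraints(2000.0))
        assert 1900 <= plan.daily_kcal <= 2100
        assert plan.compliance.status == "compliant"

    def test_missing_vegetable_group_flagged(self, food_items):
        no_veg = [f for f in food_items if f.group is not FoodGroup.VEGETABLE]
        plan = compose_plan(no_veg, constraints(2000.0))
        assert plan.compliance.status == "non_compliant"
        assert any("vegetable" in v for v in plan.compliance.violations)

    def test_deterministic_byte_identical(self, db):
        p1 = render_plan(compose_plan(db, constraints(1800.0)), "json")
        p2 = render_plan(compose_plan(db, constraints(1800.0)), "json")
        assert p1 == p2

    def test_slot_totals_sum_to_daily(self, db):
        plan = compose_plan(db, constraints(2400.0))
        assert plan.daily_kcal == pytest.approx(sum(s.kcal for s in plan.slots.values()))
        assert plan.daily_cho_g == pytest.approx(sum(s.cho_g for s in plan.slots.values()))


class TestCompliance:
    def test_cho_cap_violation_detected(self, db):
        plan = compose_plan(db, constraints(2000.0))
        plan.slots["lunch"].cho_g = 75.0
        report = check_compliance(plan, plan.constraints)
        assert not report.rules["cho_cap:lunch"]
        assert "cho_cap:lunch" in report.violations

    def test_exact_kcal_target_passes(self, db):
        plan = compose_plan(db, constraints(2000.0))
        plan.daily_kcal = 2000.0
        report = check_compliance(plan, plan.constraints)
        assert report.rules["kcal_within_tolerance"]

    def test_hand_built_toy_plan(self):
        """Three-food toy day, all four rule families checked by hand."""
        foods = [
            item("veg", kcal=50, cho=5, protein=2, fat=2.4, fiber=2, gi=10.0),
            item("cer", group=FoodGroup.CEREAL_TUBER, kcal=100, cho=20, protein=2,
                 fat=0.9, gi=52.0),
            item("prot", group=FoodGroup.ANIMAL_PROTEIN, kcal=55, cho=0, protein=8,
                 fat=2.3, gi=None),
        ]
        cons = constraints(
            1500.0,
            required_groups=(
                frozenset({FoodGroup.VEGETABLE}),
                frozenset({FoodGroup.CEREAL_TUBER}),
                frozenset({FoodGroup.LEGUME, FoodGroup.ANIMAL_PROTEIN}),
            ),
        )
        plan = compose_plan(foods, cons)
        report = plan.compliance
        # hand evaluation: all three groups present across the day
        assert report.rules["group:vegetable"]
        assert report.rules["group:cereal_tuber"]
        assert report.rules["group:animal_protein|legume"]
        # daily kcal within 5% of 1500 (composer hits every slot window)
        assert report.rules["kcal_within_tolerance"] == (
            abs(plan.daily_kcal - 1500) <= 75 + 1e-9
        )


class TestSubstitution:
    def test_substitute_keeps_compliance(self, db):
        from nutrikiosk.food_db import find_equivalents, get_food

        plan = compose_plan(db, constraints(2000.0))
        slot, fid = next(
            (s, f)
            for s in SLOTS
            for f, _ in plan.slots[s].items
            if find_equivalents(db, f, 0.10)
        )
        new_plan, notice = substitute_food(db, plan, slot, fid)
        assert notice is None
        assert new_plan.slots[slot].items != plan.slots[slot].items
        # kcal delta bounded by 10% of the replaced food's contribution
        servings = dict(plan.slots[slot].items)[fid]
        kcal_per_serving = get_food(db, fid).kcal
        assert abs(new_plan.daily_kcal - plan.daily_kcal) <= (
            0.10 * kcal_per_serving * servings + 1e-9
        )

    def test_no_equivalent_notice(self):
        foods = [
            item("solo", group=FoodGroup.DAIRY, kcal=80, cho=12, protein=8, fat=0.2, gi=32.0),
            item("veg", kcal=25, cho=4, protein=1.5, fat=0.1, gi=10.0),
        ]
        conn = init_db(foods)
        cons = constraints(1200.0, required_groups=(frozenset({FoodGroup.VEGETABLE}),))
        plan = compose_plan(conn, cons, slot_groups={"lunch": (frozenset({FoodGroup.VEGETABLE}),)})
        slot = next(s for s in SLOTS for f, _ in plan.slots[s].items if f == "solo")
        new_plan, notice = substitute_food(conn, plan, slot, "solo")
        assert notice == "no_equivalent"
        assert render_plan(new_plan, "json") == render_plan(plan, "json")

    def test_absent_food_errors(self, db):
        plan = compose_plan(db, constraints(2000.0))
        with pytest.raises(ValueError, match="not present"):
            substitute_food(db, plan, "breakfast", "no_such_food")


class TestRendering:
    def test_json_round_trip(self, db):
        plan = compose_plan(db, constraints(2000.0))
        payload = render_plan(plan, "json", triage_label="ADEQUATE")
        parsed = plan_from_json(payload)
        assert parsed["triage_label"] == "ADEQUATE"
        assert set(parsed["slots"]) == set(SLOTS)
        assert parsed["daily"]["kcal"] == round(plan.daily_kcal, 1)

    def test_text_has_five_slot_sections(self, db):
        plan = compose_plan(db, constraints(2000.0))
        text = render_plan(plan, "text")
        assert text.count("== ") == 5

    def test_consultation_advisory_line(self, db):
        plan = compose_plan(db, constraints(2000.0))
        text = render_plan(plan, "text", triage_label="REQUIRES_CONSULTATION")
        assert "ADVISORY" in text
        assert "REQUIRES_CONSULTATION" in text

    def test_unknown_format(self, db):
        plan = compose_plan(db, constraints(2000.0))
        with pytest.raises(ValueError, match="unknown format"):
            render_plan(plan, "pdf")
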