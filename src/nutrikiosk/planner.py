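"""Deterministic meal-plan composition under calorie, macronutrient,
per-meal carbohydrate, and food-group constraints.

The day is split into five slots (breakfast, mid-morning snack, lunch,
afternoon snack, dinner) with fixed calorie fractions. Each slot is filled by
a greedy pass over the food database in a fixed priority order —
diabetes-suitable first, then glycemic index ascending (missing GI last),
fiber descending, food id — adding half-serving increments while the slot
stays under its calorie ceiling and carbohydrate cap. Before the greedy fill,
each main meal seeds one food from every required food group assigned to it,
so the plan covers the essential groups across the day.

Composition is a pure function of (database contents, profile, constraints):
repeated runs give byte-identical rendered output.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .energy import MacroDistribution
from .food_db import FoodGroup, FoodItem, read_foods
from .cohort import largest_remainder

__all__ = [
    "SLOTS",
    "MAIN_MEALS",
    "PlanConstraints",
    "SlotResult",
    "MealPlan",
    "ComplianceReport",
    "allocate_meal_calories",
    "compose_meal",
    "compose_plan",
    "substitute_food",
    "check_compliance",
    "render_plan",
    "plan_from_json",
]

SLOTS = ("breakfast", "snack_am", "lunch", "snack_pm", "dinner")
MAIN_MEALS = ("breakfast", "lunch", "dinner")

DEFAULT_MEAL_FRACTIONS = {
    "breakfast": 0.25, "snack_am": 0.10, "lunch": 0.30, "snack_pm": 0.10, "dinner": 0.25,
}

#: Essential-group requirements: each inner set is satisfied by any member.
DEFAULT_REQUIRED_GROUPS: tuple[frozenset[FoodGroup], ...] = (
    frozenset({FoodGroup.VEGETABLE}),
    frozenset({FoodGroup.CEREAL_TUBER}),
    frozenset({FoodGroup.LEGUME, FoodGroup.ANIMAL_PROTEIN}),
    frozenset({FoodGroup.FRUIT}),
)

#: Which main meal seeds which required group (day-level coverage).
DEFAULT_SLOT_GROUPS: dict[str, tuple[frozenset[FoodGroup], ...]] = {
    "breakfast": (frozenset({FoodGroup.FRUIT}), frozenset({FoodGroup.CEREAL_TUBER})),
    "lunch": (
        frozenset({FoodGroup.VEGETABLE}),
        frozenset({FoodGroup.LEGUME, FoodGroup.ANIMAL_PROTEIN}),
        frozenset({FoodGroup.CEREAL_TUBER}),
    ),
    "dinner": (frozenset({FoodGroup.VEGETABLE}), frozenset({FoodGroup.CEREAL_TUBER})),
}


@dataclass(frozen=True)
class PlanConstraints:
    daily_kcal_target: float
    macro: MacroDistribution
    kcal_tolerance: float = 0.05
    cho_cap_main_g: float = 60.0
    cho_cap_snack_g: float = 25.0
    required_groups: tuple[frozenset[FoodGroup], ...] = DEFAULT_REQUIRED_GROUPS
    low_gi_threshold: float = 55.0
    serving_granularity: float = 0.5
    max_servings_per_food: float = 3.0
    meal_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAL_FRACTIONS)
    )
    diabetes_only: bool = False

    def __post_init__(self) -> None:
        if self.kcal_tolerance <= 0 or self.cho_cap_main_g <= 0 or self.cho_cap_snack_g <= 0:
            raise ValueError("caps and tolerances must be strictly positive")
        if abs(sum(self.meal_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("meal fractions must sum to 1")

    def cho_cap(self, slot: str) -> float:
        return self.cho_cap_main_g if slot in MAIN_MEALS else self.cho_cap_snack_g


@dataclass
class SlotResult:
    slot: str
    kcal_target: float
    items: list[tuple[str, float]]  # (food_id, servings), selection order
    kcal: float = 0.0
    cho_g: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    fiber_g: float = 0.0
    compliant: bool = True
    reasons: list[str] = field(default_factory=list)
    groups: set[FoodGroup] = field(default_factory=set)


@dataclass
class ComplianceReport:
    rules: dict[str, bool]
    violations: list[str]
    status: str  # "compliant" | "non_compliant"


@dataclass
class MealPlan:
    slots: dict[str, SlotResult]
    daily_kcal: float
    daily_cho_g: float
    daily_protein_g: float
    daily_fat_g: float
    daily_fiber_g: float
    constraints: PlanConstraints
    compliance: ComplianceReport | None = None


def allocate_meal_calories(
    daily_kcal: float, fractions: Mapping[str, float] | None = None
) -> dict[str, int]:
    """Whole-kcal slot targets by largest-remainder apportionment of the
    (rounded) daily total over the slot fractions; sums exactly to it."""
    fractions = fractions or DEFAULT_MEAL_FRACTIONS
    total = int(round(daily_kcal))
    counts = largest_remainder(total, [fractions[s] for s in SLOTS])
    return dict(zip(SLOTS, counts))


def candidate_order(foods: Sequence[FoodItem]) -> list[FoodItem]:
    """Fixed selection priority: diabetes-suitable first, glycemic index
    ascending with missing GI last, fiber descending, food_id."""
    return sorted(
        foods,
        key=lambda f: (
            not f.diabetes_suitable,
            f.glycemic_index is None,
            f.glycemic_index or 0.0,
            -f.fiber_g,
            f.food_id,
        ),
    )


def _add(slot: SlotResult, food: FoodItem, servings: float) -> None:
    for fid, _ in slot.items:
        if fid == food.food_id:
            slot.items = [
                (f, s + servings) if f == food.food_id else (f, s) for f, s in slot.items
            ]
            break
    else:
        slot.items.append((food.food_id, servings))
    slot.kcal += servings * food.kcal
    slot.cho_g += servings * food.cho_g
    slot.protein_g += servings * food.protein_g
    slot.fat_g += servings * food.fat_g
    slot.fiber_g += servings * food.fiber_g
    slot.groups.add(food.group)


def _exact_search(
    ordered: Sequence[FoodItem],
    lower: float,
    upper: float,
    cap: float,
    gran: float,
    max_serv: float,
) -> dict[str, float] | None:
    """Deterministic branch-and-bound over serving combinations (candidate
    order, servings tried largest first); returns the first combination whose
    energy lands in [lower, upper] with carbohydrates under the cap."""
    steps = [k * gran for k in range(int(max_serv / gran), -1, -1)]
    rem = [0.0] * (len(ordered) + 1)
    for i in range(len(ordered) - 1, -1, -1):
        rem[i] = rem[i + 1] + max_serv * ordered[i].kcal
    chosen: dict[str, float] = {}

    def dfs(i: int, kcal: float, cho: float) -> bool:
        if lower - 1e-9 <= kcal <= upper + 1e-9 and cho <= cap + 1e-9:
            return True
        if i == len(ordered) or kcal > upper + 1e-9 or cho > cap + 1e-9:
            return False
        if kcal + rem[i] < lower - 1e-9:
            return False
        food = ordered[i]
        for s in steps:
            if s > 0:
                chosen[food.food_id] = s
            else:
                chosen.pop(food.food_id, None)
            if dfs(i + 1, kcal + s * food.kcal, cho + s * food.cho_g):
                return True
        chosen.pop(food.food_id, None)
        return False

    return dict(chosen) if dfs(0, 0.0, 0.0) else None


def compose_meal(
    db_or_foods: sqlite3.Connection | Sequence[FoodItem],
    slot_kcal_target: float,
    slot_cho_cap: float,
    constraints: PlanConstraints,
    slot_name: str = "meal",
    required_groups: Sequence[frozenset[FoodGroup]] = (),
) -> SlotResult:
    """Greedy deterministic fill of one meal slot.

    Never fails silently: if the target window cannot be reached the slot is
    returned flagged non-compliant with reasons.
    """
    foods = (
        read_foods(db_or_foods)
        if isinstance(db_or_foods, sqlite3.Connection)
        else list(db_or_foods)
    )
    if constraints.diabetes_only:
        foods = [f for f in foods if f.diabetes_suitable]
    ordered = candidate_order(foods)
    gran = constraints.serving_granularity
    lower = slot_kcal_target * (1 - constraints.kcal_tolerance)
    upper = slot_kcal_target * (1 + constraints.kcal_tolerance)
    slot = SlotResult(slot=slot_name, kcal_target=slot_kcal_target, items=[])
    served: dict[str, float] = {}

    def fits(food: FoodItem, inc: float) -> bool:
        return (
            slot.kcal + inc * food.kcal <= upper + 1e-9
            and slot.cho_g + inc * food.cho_g <= slot_cho_cap + 1e-9
        )

    # Coverage pass: one seed food per required group assigned to this slot.
    for group_set in required_groups:
        if slot.groups & group_set:
            continue
        for food in ordered:
            if food.group in group_set and fits(food, gran):
                inc = 1.0 if fits(food, 1.0) else gran
                _add(slot, food, inc)
                served[food.food_id] = served.get(food.food_id, 0.0) + inc
                break
    def greedy_fill(excluded: set[str]) -> None:
        for food in ordered:
            if food.food_id in excluded:
                continue
            while (
                slot.kcal < lower - 1e-9
                and served.get(food.food_id, 0.0) + gran
                <= constraints.max_servings_per_food + 1e-9
                and fits(food, gran)
            ):
                _add(slot, food, gran)
                served[food.food_id] = served.get(food.food_id, 0.0) + gran
            if slot.kcal >= lower - 1e-9:
                return

    # Greedy fill to the calorie window, then a bounded repair loop: when the
    # carbohydrate cap leaves the slot short of calories, shrink the selected
    # food that spends the cap fastest by half a serving, bar it from further
    # additions, and refill. Deterministic; at most one pass per food.
    greedy_fill(set())
    excluded: set[str] = set()
    by_id = {f.food_id: f for f in ordered}
    while slot.kcal < lower - 1e-9:
        shrinkable = [
            by_id[fid]
            for fid, sv in slot.items
            if sv > 0 and by_id[fid].cho_g > 0 and fid not in excluded
        ]
        if not shrinkable:
            break
        victim = max(shrinkable, key=lambda f: (f.cho_g, f.food_id))
        _add(slot, victim, -gran)
        served[victim.food_id] -= gran
        excluded.add(victim.food_id)
        greedy_fill(excluded)

    slot.items = [(fid, sv) for fid, sv in slot.items if sv > 1e-9]
    slot.groups = {by_id[fid].group for fid, _ in slot.items}

    # Last resort on small candidate sets: a bounded exact search in the same
    # candidate order and serving granularity. Guarantees the composer never
    # reports infeasibility on a tiny database when a compliant combination
    # exists; real databases are served by the greedy path above.
    if slot.kcal < lower - 1e-9 and len(ordered) <= 10:
        combo = _exact_search(
            ordered, lower, upper, slot_cho_cap, gran, constraints.max_servings_per_food
        )
        if combo is not None:
            slot.items = []
            slot.kcal = slot.cho_g = slot.protein_g = slot.fat_g = slot.fiber_g = 0.0
            slot.groups = set()
            for food in ordered:
                sv = combo.get(food.food_id, 0.0)
                if sv > 0:
                    _add(slot, food, sv)

    if slot.kcal < lower - 1e-9:
        slot.compliant = False
        cho_blocked = any(
            slot.kcal + gran * f.kcal <= upper + 1e-9
            and slot.cho_g + gran * f.cho_g > slot_cho_cap + 1e-9
            for f in ordered
        )
        slot.reasons.append("cho_cap" if cho_blocked else "kcal_unreachable")
    missing = [gs for gs in required_groups if not (slot.groups & gs)]
    for gs in missing:
        slot.compliant = False
        slot.reasons.append(
            "missing_group:" + "|".join(sorted(g.value for g in gs))
        )
    return slot


def compose_plan(
    db: sqlite3.Connection | Sequence[FoodItem],
    constraints: PlanConstraints,
    slot_groups: Mapping[str, Sequence[frozenset[FoodGroup]]] | None = None,
) -> MealPlan:
    """Compose all five slots and evaluate daily compliance."""
    if slot_groups is None:
        # Seed each required group into its conventional main meal; any
        # requirement without a conventional home is seeded at lunch.
        required = list(constraints.required_groups)
        slot_groups = {
            slot: tuple(gs for gs in sets if gs in required)
            for slot, sets in DEFAULT_SLOT_GROUPS.items()
        }
        homeless = [
            gs for gs in required
            if not any(gs in sets for sets in DEFAULT_SLOT_GROUPS.values())
        ]
        if homeless:
            slot_groups["lunch"] = tuple(slot_groups.get("lunch", ())) + tuple(homeless)
    targets = allocate_meal_calories(constraints.daily_kcal_target, constraints.meal_fractions)
    slots: dict[str, SlotResult] = {}
    for name in SLOTS:
        slots[name] = compose_meal(
            db,
            targets[name],
            constraints.cho_cap(name),
            constraints,
            slot_name=name,
            required_groups=slot_groups.get(name, ()),
        )
    plan = MealPlan(
        slots=slots,
        daily_kcal=sum(s.kcal for s in slots.values()),
        daily_cho_g=sum(s.cho_g for s in slots.values()),
        daily_protein_g=sum(s.protein_g for s in slots.values()),
        daily_fat_g=sum(s.fat_g for s in slots.values()),
        daily_fiber_g=sum(s.fiber_g for s in slots.values()),
        constraints=constraints,
    )
    plan.compliance = check_compliance(plan, constraints)
    return plan


def check_compliance(plan: MealPlan, constraints: PlanConstraints) -> ComplianceReport:
    """Rule-by-rule audit: daily kcal within tolerance, per-slot carbohydrate
    caps, essential-group coverage across the day, and realized macro shares
    within the AMDR windows widened by 5 percentage points."""
    rules: dict[str, bool] = {}
    violations: list[str] = []

    target = constraints.daily_kcal_target
    ok = abs(plan.daily_kcal - target) <= constraints.kcal_tolerance * target + 1e-9
    rules["kcal_within_tolerance"] = ok
    if not ok:
        violations.append("kcal_within_tolerance")

    for name, slot in plan.slots.items():
        ok = slot.cho_g <= constraints.cho_cap(name) + 1e-9
        rules[f"cho_cap:{name}"] = ok
        if not ok:
            violations.append(f"cho_cap:{name}")

    day_groups: set[FoodGroup] = set()
    for slot in plan.slots.values():
        day_groups |= slot.groups
    for group_set in constraints.required_groups:
        key = "group:" + "|".join(sorted(g.value for g in group_set))
        ok = bool(day_groups & group_set)
        rules[key] = ok
        if not ok:
            violations.append("missing_" + key)

    atwater = 4 * plan.daily_cho_g + 4 * plan.daily_protein_g + 9 * plan.daily_fat_g
    if atwater > 0:
        shares = {
            "cho": 400 * plan.daily_cho_g / atwater,
            "protein": 400 * plan.daily_protein_g / atwater,
            "fat": 900 * plan.daily_fat_g / atwater,
        }
        windows = {"cho": (45, 65), "protein": (10, 35), "fat": (20, 35)}
        for macro, (lo, hi) in windows.items():
            ok = lo - 5 <= shares[macro] <= hi + 5
            rules[f"macro_window:{macro}"] = ok
            if not ok:
                violations.append(f"macro_window:{macro}")

    for name, slot in plan.slots.items():
        for reason in slot.reasons:
            if reason.startswith("missing_group"):
                continue  # day-level coverage already audited above
            violations.append(f"{reason}:{name}")
            rules[f"{reason}:{name}"] = False

    status = "compliant" if not violations else "non_compliant"
    return ComplianceReport(rules=rules, violations=violations, status=status)


def substitute_food(
    db: sqlite3.Connection,
    plan: MealPlan,
    slot: str,
    food_id: str,
    tolerance: float = 0.10,
) -> tuple[MealPlan, str | None]:
    """Swap one food for its nearest same-group energy equivalent, keeping the
    serving count; compliance is re-evaluated. If no equivalent exists the
    plan is returned unchanged with a ``"no_equivalent"`` notice."""
    from .food_db import find_equivalents, get_food

    if slot not in plan.slots:
        raise ValueError(f"unknown slot {slot!r}")
    slot_res = plan.slots[slot]
    servings = dict(slot_res.items).get(food_id)
    if servings is None:
        raise ValueError(f"food {food_id!r} not present in slot {slot!r}")
    equivalents = find_equivalents(db, food_id, tolerance)
    if not equivalents:
        return plan, "no_equivalent"
    replacement = equivalents[0]
    old = get_food(db, food_id)

    new_slot = SlotResult(
        slot=slot_res.slot,
        kcal_target=slot_res.kcal_target,
        items=[(replacement.food_id if f == food_id else f, s) for f, s in slot_res.items],
        kcal=slot_res.kcal + servings * (replacement.kcal - old.kcal),
        cho_g=slot_res.cho_g + servings * (replacement.cho_g - old.cho_g),
        protein_g=slot_res.protein_g + servings * (replacement.protein_g - old.protein_g),
        fat_g=slot_res.fat_g + servings * (replacement.fat_g - old.fat_g),
        fiber_g=slot_res.fiber_g + servings * (replacement.fiber_g - old.fiber_g),
        compliant=slot_res.compliant,
        reasons=list(slot_res.reasons),
        groups={
            g for g in slot_res.groups if g is not old.group
        } | {replacement.group} | (
            {old.group}
            if any(get_food(db, f).group is old.group for f, _ in slot_res.items if f != food_id)
            else set()
        ),
    )
    slots = dict(plan.slots)
    slots[slot] = new_slot
    new_plan = MealPlan(
        slots=slots,
        daily_kcal=sum(s.kcal for s in slots.values()),
        daily_cho_g=sum(s.cho_g for s in slots.values()),
        daily_protein_g=sum(s.protein_g for s in slots.values()),
        daily_fat_g=sum(s.fat_g for s in slots.values()),
        daily_fiber_g=sum(s.fiber_g for s in slots.values()),
        constraints=plan.constraints,
    )
    new_plan.compliance = check_compliance(new_plan, plan.constraints)
    return new_plan, None


# -- serialization ------------------------------------------------------------

def _plan_to_dict(plan: MealPlan, triage_label: str | None) -> dict:
    return {
        "daily": {
            "kcal_target": round(plan.constraints.daily_kcal_target, 1),
            "kcal": round(plan.daily_kcal, 1),
            "cho_g": round(plan.daily_cho_g, 1),
            "protein_g": round(plan.daily_protein_g, 1),
            "fat_g": round(plan.daily_fat_g, 1),
            "fiber_g": round(plan.daily_fiber_g, 1),
        },
        "slots": {
            name: {
                "kcal_target": round(s.kcal_target, 1),
                "kcal": round(s.kcal, 1),
                "cho_g": round(s.cho_g, 1),
                "protein_g": round(s.protein_g, 1),
                "fat_g": round(s.fat_g, 1),
                "fiber_g": round(s.fiber_g, 1),
                "items": [{"food_id": f, "servings": s_} for f, s_ in s.items],
                "compliant": s.compliant,
                "reasons": s.reasons,
            }
            for name, s in plan.slots.items()
        },
        "compliance": {
            "status": plan.compliance.status if plan.compliance else "unchecked",
            "violations": plan.compliance.violations if plan.compliance else [],
        },
        "triage_label": triage_label,
    }


_SLOT_TITLES = {
    "breakfast": "Breakfast", "snack_am": "Morning snack", "lunch": "Lunch",
    "snack_pm": "Afternoon snack", "dinner": "Dinner",
}


def render_plan(
    plan: MealPlan,
    format: str = "json",
    triage_label: str | None = None,
    food_names: Mapping[str, str] | None = None,
) -> str:
    """Serialize a plan as JSON (machine-readable, round-trips) or text
    (five slot sections, calorie summary, compliance notes; a consultation
    advisory with foods to limit when the triage label requires it)."""
    if format == "json":
        return json.dumps(_plan_to_dict(plan, triage_label), indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    names = food_names or {}
    lines = [
        "DAILY MEAL PLAN",
        f"Energy target: {plan.constraints.daily_kcal_target:.0f} kcal; "
        f"composed: {plan.daily_kcal:.0f} kcal",
        f"Macros: CHO {plan.daily_cho_g:.1f} g, protein {plan.daily_protein_g:.1f} g, "
        f"fat {plan.daily_fat_g:.1f} g, fiber {plan.daily_fiber_g:.1f} g",
        "",
    ]
    for slot_name in SLOTS:
        s = plan.slots[slot_name]
        lines.append(f"== {_SLOT_TITLES[slot_name]} ({s.kcal:.0f} kcal) ==")
        for fid, servings in s.items:
            lines.append(f"  - {names.get(fid, fid)}: {servings:g} serving(s)")
        if not s.compliant:
            lines.append(f"  [!] slot not compliant: {', '.join(s.reasons)}")
        lines.append("")
    status = plan.compliance.status if plan.compliance else "unchecked"
    lines.append(f"Compliance: {status}")
    if plan.compliance and plan.compliance.violations:
        lines.append("Violations: " + ", ".join(plan.compliance.violations))
    if triage_label is not None:
        lines.append(f"Triage: {triage_label}")
        if triage_label == "REQUIRES_CONSULTATION":
            lines.append(
                "ADVISORY: this plan requires review by a nutrition professional "
                "before use. Limit sugary drinks, sweet breads, and added sugars."
            )
    return "\n".join(lines)


def plan_from_json(payload: str) -> dict:
    """Parse a rendered JSON plan back into its dictionary form."""
    return json.loads(payload)
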