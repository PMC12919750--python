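"""The regional food-composition database.

Loads the packaged 46-food illustrative table of northern-Veracruz foods,
stores it in SQLite, lists the low-glycemic vegetables, and looks up
food-exchange equivalents for a corn tortilla.
"""

from importlib import resources

from nutrikiosk.food_db import find_equivalents, init_db, load_foods_csv, query_by_group

foods_csv = resources.files("nutrikiosk") / "data" / "foods.csv"
items, rejected = load_foods_csv(str(foods_csv))
print(f"loaded {len(items)} foods ({len(rejected)} rejected)")

db = init_db(items)

print("\nDiabetes-suitable vegetables with glycemic index <= 55 (best first):")
for f in query_by_group(db, "vegetable", diabetes_only=True, max_gi=55):
    print(f"  {f.name:<22} GI {f.glycemic_index:>4.0f}  fiber {f.fiber_g:.1f} g  {f.kcal:.0f} kcal")

print("\nExchange equivalents for 'tortilla_maiz' (same group, kcal within 10%):")
for f in find_equivalents(db, "tortilla_maiz", 0.10):
    print(f"  {f.name:<22} {f.kcal:.0f} kcal per {f.serving_desc}")
print("\nEquivalents let a patient swap foods without breaking the plan's energy budget.")
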