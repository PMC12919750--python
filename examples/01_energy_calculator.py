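"""Energy requirements for one patient profile.

Computes BMI, basal metabolic rate (revised Harris-Benedict), total daily
energy expenditure with an activity multiplier clamped to the kiosk's
1200-2800 kcal/day operating range, and the daily macronutrient targets in
grams for a 50/20/30 carbohydrate/protein/fat split.
"""

from nutrikiosk.energy import (
    ActivityLevel,
    Anthropometrics,
    MacroDistribution,
    Sex,
    compute_bmi,
    macro_split,
    total_energy,
)

profile = Anthropometrics(age_years=40, sex=Sex.MALE, height_m=1.75, weight_kg=70.0)
req = total_energy(profile, ActivityLevel.MODERATE)
grams = macro_split(req.tdee_kcal, MacroDistribution(50, 20, 30))

print(f"BMI:               {compute_bmi(profile)} kg/m^2")
print(f"BMR:               {req.bmr_kcal} kcal/day")
print(f"TDEE:              {req.tdee_kcal} kcal/day (clamped: {req.clamped})")
print(f"Daily macros:      {grams['cho_g']} g CHO, {grams['protein_g']} g protein, "
      f"{grams['fat_g']} g fat")
print()
print("TDEE = BMR x activity factor; the macro grams reconvert to the TDEE")
print("via the Atwater densities 4/4/9 kcal per gram.")
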