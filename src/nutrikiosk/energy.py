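"""Energy-requirement calculations: BMI, basal metabolic rate, total daily
energy expenditure, and the macronutrient split in grams.

The basal rate uses the revised (1984, Roza-Shizgal) Harris-Benedict
coefficients by default; the original 1919 coefficients are available through
``variant="original"``. Total energy is the basal rate times a conventional
physical-activity multiplier, clamped into the 1200-2800 kcal/day window the
rest of the system (cohort simulator, planner) is designed around.

Rounding is fixed so downstream output is stable: BMI to 2 decimals, energy to
2 decimals, macro grams to 1 decimal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Sex",
    "ActivityLevel",
    "Anthropometrics",
    "EnergyRequirement",
    "MacroDistribution",
    "KCAL_MIN",
    "KCAL_MAX",
    "compute_bmi",
    "basal_metabolic_rate",
    "total_energy",
    "macro_split",
]

KCAL_MIN = 1200.0
KCAL_MAX = 2800.0

#: kcal per gram of carbohydrate, protein, fat (Atwater factors).
ATWATER = {"cho": 4.0, "protein": 4.0, "fat": 9.0}


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class ActivityLevel(str, enum.Enum):
    """Physical-activity categories with conventional Harris-Benedict multipliers."""

    SEDENTARY = "sedentary"
    LIGHT = "light"
    MODERATE = "moderate"
    ACTIVE = "active"
    VERY_ACTIVE = "very_active"

    @property
    def factor(self) -> float:
        return _ACTIVITY_FACTORS[self]


_ACTIVITY_FACTORS = {
    ActivityLevel.SEDENTARY: 1.2,
    ActivityLevel.LIGHT: 1.375,
    ActivityLevel.MODERATE: 1.55,
    ActivityLevel.ACTIVE: 1.725,
    ActivityLevel.VERY_ACTIVE: 1.9,
}


@dataclass(frozen=True)
class Anthropometrics:
    """Validated anthropometric input record.

    Ranges mirror the kiosk's input validation: age > 0 years, height in
    (0.5, 2.5) m, weight in (20, 300) kg.
    """

    age_years: int
    sex: Sex
    height_m: float
    weight_kg: float

    def __post_init__(self) -> None:
        if not isinstance(self.age_years, int) or self.age_years <= 0:
            raise ValueError(f"age_years must be a positive integer, got {self.age_years!r}")
        object.__setattr__(self, "sex", Sex(self.sex))
        if not 0.5 < self.height_m < 2.5:
            raise ValueError(f"height_m must be in (0.5, 2.5), got {self.height_m}")
        if not 20 < self.weight_kg < 300:
            raise ValueError(f"weight_kg must be in (20, 300), got {self.weight_kg}")


@dataclass(frozen=True)
class EnergyRequirement:
    bmr_kcal: float
    tdee_kcal: float
    clamped: bool


@dataclass(frozen=True)
class MacroDistribution:
    """Percent-of-energy split, constrained to the adult AMDR windows:
    carbohydrate 45-65%, protein 10-35%, fat 20-35%, summing to 100."""

    cho_pct: float
    protein_pct: float
    fat_pct: float

    def __post_init__(self) -> None:
        if abs(self.cho_pct + self.protein_pct + self.fat_pct - 100.0) > 1e-9:
            raise ValueError(
                "macro percentages must sum to 100, got "
                f"{self.cho_pct + self.protein_pct + self.fat_pct}"
            )
        for name, value, lo, hi in (
            ("cho_pct", self.cho_pct, 45, 65),
            ("protein_pct", self.protein_pct, 10, 35),
            ("fat_pct", self.fat_pct, 20, 35),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


# Revised Harris-Benedict (Roza & Shizgal 1984) and original 1919 coefficients:
# intercept, weight (kg), height (cm), age (years).
_HB_COEFFS = {
    "revised": {
        Sex.MALE: (88.362, 13.397, 4.799, -5.677),
        Sex.FEMALE: (447.593, 9.247, 3.098, -4.330),
    },
    "original": {
        Sex.MALE: (66.4730, 13.7516, 5.0033, -6.7550),
        Sex.FEMALE: (655.0955, 9.5634, 1.8496, -4.6756),
    },
}


def compute_bmi(a: Anthropometrics) -> float:
    """Body mass index, weight / height^2, to 2 decimals."""
    return round(a.weight_kg / a.height_m**2, 2)


def basal_metabolic_rate(a: Anthropometrics, variant: str = "revised") -> float:
    """Harris-Benedict basal metabolic rate in kcal/day, to 2 decimals."""
    try:
        c0, cw, ch, ca = _HB_COEFFS[variant][a.sex]
    except KeyError:
        raise ValueError(f"unknown Harris-Benedict variant {variant!r}") from None
    bmr = c0 + cw * a.weight_kg + ch * (a.height_m * 100.0) + ca * a.age_years
    return round(bmr, 2)


def total_energy(
    a: Anthropometrics, act: ActivityLevel, variant: str = "revised"
) -> EnergyRequirement:
    """BMR times the activity multiplier, clamped into [1200, 2800] kcal/day.

    The clamp keeps every user profile inside the regime the recommendation
    model was trained on; ``clamped`` is exposed so callers can warn.
    """
    bmr = basal_metabolic_rate(a, variant=variant)
    raw = bmr * ActivityLevel(act).factor
    tdee = min(max(raw, KCAL_MIN), KCAL_MAX)
    return EnergyRequirement(
        bmr_kcal=bmr, tdee_kcal=round(tdee, 2), clamped=abs(tdee - raw) > 1e-9
    )


def macro_split(tdee_kcal: float, dist: MacroDistribution) -> dict[str, float]:
    """Daily macro targets in grams (1 decimal) from a kcal total and a
    percent-of-energy distribution, using Atwater densities 4/4/9."""
    return {
        "cho_g": round(dist.cho_pct / 100.0 * tdee_kcal / ATWATER["cho"], 1),
        "protein_g": round(dist.protein_pct / 100.0 * tdee_kcal / ATWATER["protein"], 1),
        "fat_g": round(dist.fat_pct / 100.0 * tdee_kcal / ATWATER["fat"], 1),
    }
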