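"""Synthetic diabetic-cohort simulator.

Generates the training population for the plan-triage classifier: records with
15 coded variables (demographic, clinical, and nutritional) plus a
three-class disposition label, drawn by stratified sampling with
physiological and consistency filters.

Strata follow the diabetes-type mix of the Mexican adult population with
diabetes (type 2 dominant); within a stratum, anthropometrics and dietary
patterns vary around survey-like central values. Glycemic control drives
correlated behaviour: poorly controlled patients are more likely to report
low adherence and a sugar- or fat-predominant diet, which is what makes the
"requires consultation" class reachable.

The label is a deterministic, auditable violation-point score (see
``assign_label``); optional uniform label noise emulates expert disagreement
so a classifier trained on these labels plateaus below 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .energy import (
    ActivityLevel,
    Anthropometrics,
    Sex,
    compute_bmi,
    total_energy,
)
from .food_db import FoodGroup

__all__ = [
    "LABELS",
    "CohortRecord",
    "StratumSpec",
    "CohortConfig",
    "sample_stratified",
    "apply_filters",
    "assign_label",
    "generate_cohort",
    "inject_label_noise",
    "split_train_test",
    "export_csv",
    "import_csv",
    "largest_remainder",
]

LABELS = ("ADEQUATE", "MINOR_ADJUSTMENT", "REQUIRES_CONSULTATION")

DIABETES_TYPES = ("type2", "type1", "prediabetes")
GLYCEMIC_CONTROL = ("good", "fair", "poor")
ADHERENCE = ("low", "medium", "high")
PREFERENCE = ("omnivore", "low_meat", "vegetarian")

BMI_MIN, BMI_MAX = 15.0, 40.0

#: The 15 feature columns, in canonical CSV order; the label comes last.
FEATURE_COLUMNS = [
    "age_years",
    "sex",
    "height_m",
    "weight_kg",
    "bmi",
    "diabetes_type",
    "glycemic_control",
    "activity_level",
    "kcal_need",
    "cho_pct",
    "protein_pct",
    "fat_pct",
    "predominant_food_group",
    "dietary_adherence",
    "food_preference",
]
CSV_COLUMNS = FEATURE_COLUMNS + ["label"]


@dataclass(frozen=True)
class CohortRecord:
    age_years: int
    sex: str
    height_m: float
    weight_kg: float
    bmi: float
    diabetes_type: str
    glycemic_control: str
    activity_level: str
    kcal_need: float
    cho_pct: float
    protein_pct: float
    fat_pct: float
    predominant_food_group: str
    dietary_adherence: str
    food_preference: str
    label: str = ""


_FOOD_GROUPS = [g.value for g in FoodGroup]

# Predominant-food-group sampling weights. Poorly controlled patients skew
# toward sugar/fat-predominant diets; others toward the plate-model staples.
_GROUP_PROBS_CONTROLLED = {
    "cereal_tuber": 0.30, "legume": 0.16, "vegetable": 0.22, "fruit": 0.10,
    "animal_protein": 0.12, "dairy": 0.04, "fats_oils": 0.03, "sugar_sweet": 0.03,
}
_GROUP_PROBS_POOR = {
    "cereal_tuber": 0.24, "legume": 0.08, "vegetable": 0.08, "fruit": 0.08,
    "animal_protein": 0.10, "dairy": 0.07, "fats_oils": 0.15, "sugar_sweet": 0.20,
}


@dataclass(frozen=True)
class StratumSpec:
    """Sampling parameters for one cohort stratum (one diabetes type)."""

    name: str
    weight: float
    diabetes_type: str
    age_range: tuple[int, int] = (30, 75)
    female_prob: float = 0.55
    height_mean: dict | None = None          # per sex; defaults below
    bmi_mean: float = 29.0
    bmi_sd: float = 4.8
    glycemic_control_probs: tuple[float, float, float] = (0.36, 0.32, 0.32)
    activity_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)
    adherence_probs_controlled: tuple[float, float, float] = (0.28, 0.38, 0.34)
    adherence_probs_poor: tuple[float, float, float] = (0.50, 0.30, 0.20)
    preference_probs: tuple[float, float, float] = (0.80, 0.14, 0.06)

    def __post_init__(self) -> None:
        if self.diabetes_type not in DIABETES_TYPES:
            raise ValueError(f"unknown diabetes_type {self.diabetes_type!r}")
        if not 0 <= self.weight <= 1:
            raise ValueError("stratum weight must be in [0, 1]")


_DEFAULT_HEIGHT = {"female": (1.58, 0.06), "male": (1.70, 0.07)}


def default_strata() -> list[StratumSpec]:
    """Diabetes-type mix shaped like the national adult diabetes population
    (type 2 dominant); weights are configurable placeholders, not survey
    microdata."""
    return [
        StratumSpec(name="type2", weight=0.80, diabetes_type="type2"),
        StratumSpec(name="type1", weight=0.08, diabetes_type="type1",
                    age_range=(18, 60), bmi_mean=26.0, bmi_sd=4.2),
        StratumSpec(name="prediabetes", weight=0.12, diabetes_type="prediabetes",
                    bmi_mean=28.5, bmi_sd=4.5,
                    glycemic_control_probs=(0.55, 0.30, 0.15)),
    ]


@dataclass(frozen=True)
class CohortConfig:
    n_target: int = 10_000
    seed: int = 0
    strata: tuple[StratumSpec, ...] = field(default_factory=lambda: tuple(default_strata()))
    label_noise_rate: float = 0.12
    class_targets: tuple[float, float, float] = (0.55, 0.30, 0.15)
    max_retries_per_record: int = 50

    def __post_init__(self) -> None:
        if self.n_target <= 0:
            raise ValueError("n_target must be positive")
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum weights sum to {total}, expected 1")
        if not 0 <= self.label_noise_rate < 0.5:
            raise ValueError("label_noise_rate must be in [0, 0.5)")
        if abs(sum(self.class_targets) - 1.0) > 1e-9:
            raise ValueError("class_targets must sum to 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        if "strata" in raw:
            raw["strata"] = tuple(
                StratumSpec(**{**s, "age_range": tuple(s.get("age_range", (30, 75)))})
                for s in raw["strata"]
            )
        for key in ("class_targets",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def largest_remainder(n: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer counts proportional to ``weights`` using
    the largest-remainder (Hamilton) method; ties broken by position."""
    quotas = [n * w for w in weights]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _sample_raw(stratum: StratumSpec, rng: np.random.Generator) -> CohortRecord:
    sex = "female" if rng.random() < stratum.female_prob else "male"
    h_mean, h_sd = (stratum.height_mean or _DEFAULT_HEIGHT)[sex]
    height = float(np.clip(rng.normal(h_mean, h_sd), 1.40, 2.00))
    height = round(height, 2)
    age = int(rng.integers(stratum.age_range[0], stratum.age_range[1] + 1))
    bmi_draw = rng.normal(stratum.bmi_mean, stratum.bmi_sd)
    weight = round(bmi_draw * height**2, 1)
    weight = float(np.clip(weight, 25.0, 280.0))
    control = str(rng.choice(GLYCEMIC_CONTROL, p=stratum.glycemic_control_probs))
    activity = str(rng.choice([a.value for a in ActivityLevel], p=stratum.activity_probs))
    if control == "poor":
        adherence_probs = stratum.adherence_probs_poor
        group_probs = _GROUP_PROBS_POOR
    else:
        adherence_probs = stratum.adherence_probs_controlled
        group_probs = _GROUP_PROBS_CONTROLLED
    adherence = str(rng.choice(ADHERENCE, p=adherence_probs))
    group = str(rng.choice(list(group_probs), p=list(group_probs.values())))
    preference = str(rng.choice(PREFERENCE, p=stratum.preference_probs))

    cho = round(float(rng.uniform(45, 65)), 1)
    fat_hi = min(35.0, 90.0 - cho)
    fat = round(float(rng.uniform(20, fat_hi)), 1)
    protein = round(100.0 - cho - fat, 1)

    anthro = Anthropometrics(age_years=age, sex=Sex(sex), height_m=height, weight_kg=weight)
    req = total_energy(anthro, ActivityLevel(activity))
    return CohortRecord(
        age_years=age, sex=sex, height_m=height, weight_kg=weight,
        bmi=compute_bmi(anthro), diabetes_type=stratum.diabetes_type,
        glycemic_control=control, activity_level=activity,
        kcal_need=req.tdee_kcal, cho_pct=cho, protein_pct=protein, fat_pct=fat,
        predominant_food_group=group, dietary_adherence=adherence,
        food_preference=preference,
    )


def sample_stratified(cfg: CohortConfig, rng: np.random.Generator | None = None):
    """Yield ``cfg.n_target`` raw (unfiltered, unlabeled) records, stratum
    counts apportioned by largest remainder. Deterministic for a fixed seed."""
    rng = rng or np.random.default_rng(cfg.seed)
    counts = largest_remainder(cfg.n_target, [s.weight for s in cfg.strata])
    for stratum, count in zip(cfg.strata, counts):
        for _ in range(count):
            yield _sample_raw(stratum, rng)


def record_violations(rec: CohortRecord) -> list[str]:
    """Consistency-filter violations for one record (empty list = passes)."""
    reasons = []
    if not BMI_MIN <= rec.bmi <= BMI_MAX:
        reasons.append("bmi_out_of_range")
    if not 1200 <= rec.kcal_need <= 2800:
        reasons.append("kcal_range")
    if abs(rec.cho_pct + rec.protein_pct + rec.fat_pct - 100.0) > 0.05:
        reasons.append("macro_sum")
    if not (45 <= rec.cho_pct <= 65 and 10 <= rec.protein_pct <= 35 and 20 <= rec.fat_pct <= 35):
        reasons.append("macro_window")
    if rec.sex not in ("female", "male") or rec.diabetes_type not in DIABETES_TYPES:
        reasons.append("bad_category")
    return reasons


def apply_filters(records: Sequence[CohortRecord]) -> tuple[list[CohortRecord], dict[str, int]]:
    """Drop records violating physiological/consistency rules; tally reasons."""
    survivors: list[CohortRecord] = []
    tally: dict[str, int] = {}
    for rec in records:
        reasons = record_violations(rec)
        if reasons:
            for r in reasons:
                tally[r] = tally.get(r, 0) + 1
        else:
            survivors.append(rec)
    return survivors, tally


def assign_label(rec: CohortRecord) -> str:
    """Deterministic triage label from violation points.

    Points: poor glycemic control (2); type 1 or prediabetes with
    carbohydrate share above 55% of energy (1); low dietary adherence (1);
    BMI outside [18.5, 30] (1); sugar- or fat-predominant diet (2).
    0-1 points -> ADEQUATE, 2-3 -> MINOR_ADJUSTMENT, >=4 -> REQUIRES_CONSULTATION.
    """
    points = 0
    if rec.glycemic_control == "poor":
        points += 2
    if rec.diabetes_type in ("type1", "prediabetes") and rec.cho_pct > 55:
        points += 1
    if rec.dietary_adherence == "low":
        points += 1
    if not 18.5 <= rec.bmi <= 30:
        points += 1
    if rec.predominant_food_group in ("sugar_sweet", "fats_oils"):
        points += 2
    if points <= 1:
        return "ADEQUATE"
    if points <= 3:
        return "MINOR_ADJUSTMENT"
    return "REQUIRES_CONSULTATION"


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[list[CohortRecord], dict[str, int]]:
    """Full pipeline: stratified sampling, filters with per-stratum resampling
    until ``n_target`` survivors, deterministic labeling, then label noise.

    Returns the labeled cohort and the rejection tally. Raises ``RuntimeError``
    if a stratum cannot produce its quota within the retry budget (an
    infeasible stratum spec).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = largest_remainder(cfg.n_target, [s.weight for s in cfg.strata])
    cohort: list[CohortRecord] = []
    tally: dict[str, int] = {}
    for stratum, count in zip(cfg.strata, counts):
        kept = 0
        budget = count * cfg.max_retries_per_record
        while kept < count:
            if budget <= 0:
                raise RuntimeError(
                    f"stratum {stratum.name!r}: retry budget exhausted; "
                    "sampling ranges are inconsistent with the filters"
                )
            rec = _sample_raw(stratum, rng)
            budget -= 1
            reasons = record_violations(rec)
            if reasons:
                for r in reasons:
                    tally[r] = tally.get(r, 0) + 1
                continue
            cohort.append(replace(rec, label=assign_label(rec)))
            kept += 1
    if cfg.label_noise_rate > 0:
        cohort, _ = inject_label_noise(cohort, cfg.label_noise_rate, rng)
    return cohort, tally


def inject_label_noise(
    records: Sequence[CohortRecord],
    rate: float,
    rng_or_seed: np.random.Generator | int,
) -> tuple[list[CohortRecord], list[tuple[int, str, str]]]:
    """Independently replace each label, with probability ``rate``, by one of
    the other two classes uniformly. Returns records and a flip log of
    (index, old_label, new_label)."""
    if not 0 <= rate < 0.5:
        raise ValueError("rate must be in [0, 0.5)")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    out: list[CohortRecord] = []
    log: list[tuple[int, str, str]] = []
    for i, rec in enumerate(records):
        if rate > 0 and rng.random() < rate:
            others = [lb for lb in LABELS if lb != rec.label]
            new = others[int(rng.integers(0, 2))]
            log.append((i, rec.label, new))
            out.append(replace(rec, label=new))
        else:
            out.append(rec)
    return out, log


def split_train_test(
    records: Sequence[CohortRecord], fraction: float, seed: int
) -> tuple[list[CohortRecord], list[CohortRecord]]:
    """Label-stratified split into train (``round(n*fraction)``) and test.

    Per-class train counts are the largest-remainder apportionment of the
    train total across classes, so overall and per-class proportions match to
    within one record.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(records)
    by_label: dict[str, list[int]] = {lb: [] for lb in LABELS}
    for i, rec in enumerate(records):
        if rec.label not in by_label:
            raise ValueError(f"unknown label {rec.label!r}")
        by_label[rec.label].append(i)
    for lb, idx in by_label.items():
        if 0 < len(idx) < 2:
            raise ValueError(f"label class {lb} has fewer than 2 members")
    present = [lb for lb in LABELS if by_label[lb]]
    train_total = round(n * fraction)
    class_sizes = [len(by_label[lb]) for lb in present]
    train_counts = largest_remainder(train_total, [c / n for c in class_sizes])
    # Guard degenerate apportionment: keep at least one test record per class.
    train_counts = [min(tc, cs - 1) for tc, cs in zip(train_counts, class_sizes)]
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lb, tc in zip(present, train_counts):
        idx = np.array(by_label[lb])
        rng.shuffle(idx)
        train_idx.extend(idx[:tc].tolist())
        test_idx.extend(idx[tc:].tolist())
    train_idx.sort()
    test_idx.sort()
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def to_dataframe(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)


def export_csv(records: Sequence[CohortRecord], path: str | Path) -> None:
    to_dataframe(records).to_csv(path, index=False)


def import_csv(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV, re-validating every row against the cohort
    invariants; malformed rows raise with the offending row and reason."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {', '.join(missing)}")
    records: list[CohortRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = CohortRecord(
            age_years=int(row.age_years), sex=str(row.sex),
            height_m=float(row.height_m), weight_kg=float(row.weight_kg),
            bmi=float(row.bmi), diabetes_type=str(row.diabetes_type),
            glycemic_control=str(row.glycemic_control),
            activity_level=str(row.activity_level), kcal_need=float(row.kcal_need),
            cho_pct=float(row.cho_pct), protein_pct=float(row.protein_pct),
            fat_pct=float(row.fat_pct),
            predominant_food_group=str(row.predominant_food_group),
            dietary_adherence=str(row.dietary_adherence),
            food_preference=str(row.food_preference), label=str(row.label),
        )
        reasons = record_violations(rec)
        if reasons:
            raise ValueError(f"row {i}: invariant violation(s): {', '.join(reasons)}")
        if rec.label not in LABELS:
            raise ValueError(f"row {i}: unknown label {rec.label!r}")
        records.append(rec)
    return records
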