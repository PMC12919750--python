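"""Regional food-composition database: CSV ingestion with consistency checks,
SQLite storage, group queries, and food-exchange (equivalent) lookup.

Food groups follow the 8-category Mexican dietary-guidance plate scheme
(NOM-043 style): cereals and tubers, legumes, vegetables, fruits, animal
protein, dairy, fats and oils, sugars and sweets.

Every accepted record must pass an Atwater energy-consistency check:
4*cho + 4*protein + 9*fat within +-20% of the declared kcal per serving. The
20% band absorbs fiber and rounding effects present in published composition
tables.
"""

from __future__ import annotations

import csv
import enum
import sqlite3
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FoodGroup",
    "FoodItem",
    "Recipe",
    "RejectedRow",
    "FoodDBError",
    "load_foods_csv",
    "load_recipes_csv",
    "init_db",
    "open_db",
    "read_foods",
    "query_by_group",
    "find_equivalents",
    "get_food",
]

ATWATER_TOLERANCE = 0.20
GI_MAX = 110.0

FOODS_COLUMNS = [
    "food_id",
    "name",
    "group",
    "serving_desc",
    "serving_g",
    "kcal",
    "cho_g",
    "protein_g",
    "fat_g",
    "fiber_g",
    "glycemic_index",
    "diabetes_suitable",
    "regional",
]

RECIPES_COLUMNS = ["recipe_id", "name", "food_id", "servings", "meal_slots"]


class FoodGroup(str, enum.Enum):
    CEREAL_TUBER = "cereal_tuber"
    LEGUME = "legume"
    VEGETABLE = "vegetable"
    FRUIT = "fruit"
    ANIMAL_PROTEIN = "animal_protein"
    DAIRY = "dairy"
    FATS_OILS = "fats_oils"
    SUGAR_SWEET = "sugar_sweet"


class FoodDBError(Exception):
    """Raised for database-level failures (duplicates, unknown ids, empty input)."""


@dataclass(frozen=True)
class FoodItem:
    food_id: str
    name: str
    group: FoodGroup
    serving_desc: str
    serving_g: float
    kcal: float
    cho_g: float
    protein_g: float
    fat_g: float
    fiber_g: float
    glycemic_index: float | None
    diabetes_suitable: bool
    regional: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", FoodGroup(self.group))
        if self.serving_g <= 0:
            raise ValueError(f"{self.food_id}: serving_g must be > 0")
        for name in ("kcal", "cho_g", "protein_g", "fat_g", "fiber_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.food_id}: {name} must be >= 0")
        if self.glycemic_index is not None and not 0 <= self.glycemic_index <= GI_MAX:
            raise ValueError(
                f"{self.food_id}: glycemic_index {self.glycemic_index} outside [0, {GI_MAX}]"
            )
        atwater = 4 * self.cho_g + 4 * self.protein_g + 9 * self.fat_g
        if abs(atwater - self.kcal) > ATWATER_TOLERANCE * self.kcal:
            raise ValueError(
                f"{self.food_id}: Atwater energy {atwater:.1f} kcal deviates more than "
                f"{ATWATER_TOLERANCE:.0%} from declared {self.kcal:.1f} kcal"
            )


@dataclass(frozen=True)
class Recipe:
    recipe_id: str
    name: str
    components: tuple[tuple[str, float], ...]  # (food_id, servings)
    meal_slots: tuple[str, ...]


@dataclass(frozen=True)
class RejectedRow:
    row_index: int  # 1-based data-row index
    reason: str


_MANDATORY = [c for c in FOODS_COLUMNS if c != "glycemic_index"]


def _parse_bool(raw: str) -> bool:
    v = raw.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def load_foods_csv(
    path: str | Path, strict: bool = False
) -> tuple[list[FoodItem], list[RejectedRow]]:
    """Read a foods CSV (UTF-8, comma, header mandatory) into validated items.

    Returns accepted items in input order plus a rejection report with one
    reason code per bad row. In strict mode the first invalid row aborts the
    load with ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in FOODS_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"foods CSV missing mandatory column(s): {', '.join(missing)}")
        items: list[FoodItem] = []
        rejected: list[RejectedRow] = []
        for i, row in enumerate(reader, start=1):
            try:
                items.append(_parse_food_row(row))
            except ValueError as exc:
                if strict:
                    raise ValueError(f"row {i}: {exc}") from exc
                rejected.append(RejectedRow(row_index=i, reason=str(exc)))
    return items, rejected


def _parse_food_row(row: dict[str, str]) -> FoodItem:
    for col in _MANDATORY:
        if not (row.get(col) or "").strip():
            raise ValueError(f"missing {col}")
    gi_raw = (row.get("glycemic_index") or "").strip()
    return FoodItem(
        food_id=row["food_id"].strip(),
        name=row["name"].strip(),
        group=FoodGroup(row["group"].strip()),
        serving_desc=row["serving_desc"].strip(),
        serving_g=float(row["serving_g"]),
        kcal=float(row["kcal"]),
        cho_g=float(row["cho_g"]),
        protein_g=float(row["protein_g"]),
        fat_g=float(row["fat_g"]),
        fiber_g=float(row["fiber_g"]),
        glycemic_index=float(gi_raw) if gi_raw else None,
        diabetes_suitable=_parse_bool(row["diabetes_suitable"]),
        regional=_parse_bool(row["regional"]),
    )


def load_recipes_csv(path: str | Path, known_food_ids: set[str]) -> list[Recipe]:
    """Read a recipes CSV (one row per component) into Recipe records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grouped: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in RECIPES_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"recipes CSV missing column(s): {', '.join(missing)}")
        for row in reader:
            rid = row["recipe_id"].strip()
            food_id = row["food_id"].strip()
            if food_id not in known_food_ids:
                raise ValueError(f"recipe {rid}: unknown component food_id {food_id!r}")
            servings = float(row["servings"])
            if servings < 0:
                raise ValueError(f"recipe {rid}: negative servings")
            entry = grouped.setdefault(
                rid,
                {"name": row["name"].strip(), "components": [], "meal_slots": row["meal_slots"].strip()},
            )
            entry["components"].append((food_id, servings))
    return [
        Recipe(
            recipe_id=rid,
            name=e["name"],
            components=tuple(e["components"]),
            meal_slots=tuple(s for s in e["meal_slots"].split(";") if s),
        )
        for rid, e in grouped.items()
    ]


_SCHEMA = """
CREATE TABLE foods (
    food_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    food_group TEXT NOT NULL,
    serving_desc TEXT NOT NULL,
    serving_g REAL NOT NULL CHECK (serving_g > 0),
    kcal REAL NOT NULL CHECK (kcal >= 0),
    cho_g REAL NOT NULL CHECK (cho_g >= 0),
    protein_g REAL NOT NULL CHECK (protein_g >= 0),
    fat_g REAL NOT NULL CHECK (fat_g >= 0),
    fiber_g REAL NOT NULL CHECK (fiber_g >= 0),
    glycemic_index REAL,
    diabetes_suitable INTEGER NOT NULL,
    regional INTEGER NOT NULL
);
CREATE TABLE recipes (
    recipe_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    meal_slots TEXT NOT NULL
);
CREATE TABLE recipe_components (
    recipe_id TEXT NOT NULL REFERENCES recipes(recipe_id),
    food_id TEXT NOT NULL REFERENCES foods(food_id),
    servings REAL NOT NULL CHECK (servings >= 0),
    PRIMARY KEY (recipe_id, food_id)
);
"""


def init_db(
    items: Sequence[FoodItem],
    recipes: Sequence[Recipe] = (),
    path: str | Path = ":memory:",
) -> sqlite3.Connection:
    """Create a fresh SQLite food database and load items and recipes.

    The resulting file is readable with standard SQLite tooling; a round-trip
    read returns records identical to the input.
    """
    if not items:
        raise FoodDBError("empty food database")
    seen: set[str] = set()
    for it in items:
        if it.food_id in seen:
            raise FoodDBError(f"duplicate food_id: {it.food_id}")
        seen.add(it.food_id)
    path = str(path)
    if path != ":memory:":
        p = Path(path)
        if p.exists():
            p.unlink()
    conn = sqlite3.connect(path)
    conn.executescript(_SCHEMA)
    conn.executemany(
        "INSERT INTO foods VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
        [
            (
                it.food_id, it.name, it.group.value, it.serving_desc, it.serving_g,
                it.kcal, it.cho_g, it.protein_g, it.fat_g, it.fiber_g,
                it.glycemic_index, int(it.diabetes_suitable), int(it.regional),
            )
            for it in items
        ],
    )
    for r in recipes:
        for food_id, _ in r.components:
            if food_id not in seen:
                raise FoodDBError(f"recipe {r.recipe_id}: unknown food_id {food_id}")
        conn.execute(
            "INSERT INTO recipes VALUES (?,?,?)",
            (r.recipe_id, r.name, ";".join(r.meal_slots)),
        )
        conn.executemany(
            "INSERT INTO recipe_components VALUES (?,?,?)",
            [(r.recipe_id, fid, sv) for fid, sv in r.components],
        )
    conn.commit()
    return conn


def open_db(path: str | Path) -> sqlite3.Connection:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return sqlite3.connect(str(p))


def _row_to_item(row: tuple) -> FoodItem:
    return FoodItem(
        food_id=row[0], name=row[1], group=FoodGroup(row[2]), serving_desc=row[3],
        serving_g=row[4], kcal=row[5], cho_g=row[6], protein_g=row[7], fat_g=row[8],
        fiber_g=row[9], glycemic_index=row[10],
        diabetes_suitable=bool(row[11]), regional=bool(row[12]),
    )


def read_foods(db: sqlite3.Connection) -> list[FoodItem]:
    """All stored foods, in insertion (rowid) order."""
    rows = db.execute("SELECT * FROM foods ORDER BY rowid").fetchall()
    return [_row_to_item(r) for r in rows]


def get_food(db: sqlite3.Connection, food_id: str) -> FoodItem:
    row = db.execute("SELECT * FROM foods WHERE food_id = ?", (food_id,)).fetchone()
    if row is None:
        raise FoodDBError(f"unknown food_id: {food_id}")
    return _row_to_item(row)


def _gi_sort_key(item: FoodItem) -> tuple:
    # Missing glycemic index sorts after every item that has one.
    gi_missing = item.glycemic_index is None
    return (gi_missing, item.glycemic_index or 0.0, -item.fiber_g, item.food_id)


def query_by_group(
    db: sqlite3.Connection,
    group: FoodGroup | str,
    diabetes_only: bool = False,
    max_gi: float | None = None,
) -> list[FoodItem]:
    """Foods of a group, optionally restricted to diabetes-suitable and/or a
    glycemic-index ceiling; sorted GI ascending (missing GI last), fiber
    descending, food_id as final tie-break."""
    group = FoodGroup(group)
    items = [it for it in read_foods(db) if it.group is group]
    if diabetes_only:
        items = [it for it in items if it.diabetes_suitable]
    if max_gi is not None:
        items = [it for it in items if it.glycemic_index is not None and it.glycemic_index <= max_gi]
    return sorted(items, key=_gi_sort_key)


def find_equivalents(
    db: sqlite3.Connection, food_id: str, kcal_tolerance_fraction: float = 0.10
) -> list[FoodItem]:
    """Food-exchange lookup: same group, energy per serving within the given
    fraction of the query food's kcal, sorted by absolute kcal difference."""
    if not 0 < kcal_tolerance_fraction <= 1:
        raise ValueError("kcal_tolerance_fraction must be in (0, 1]")
    query = get_food(db, food_id)
    out = [
        it
        for it in read_foods(db)
        if it.group is query.group
        and it.food_id != food_id
        and abs(it.kcal - query.kcal) <= kcal_tolerance_fraction * query.kcal
    ]
    return sorted(out, key=lambda it: (abs(it.kcal - query.kcal), it.food_id))


def items_equal(a: Iterable[FoodItem], b: Iterable[FoodItem]) -> bool:
    """Field-by-field equality of two item sequences (round-trip checks)."""
    la, lb = list(a), list(b)
    if len(la) != len(lb):
        return False
    for x, y in zip(la, lb):
        for f in dc_fields(FoodItem):
            if getattr(x, f.name) != getattr(y, f.name):
                return False
    return True
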