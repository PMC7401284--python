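"""Food composition data and high/low nutrient-density categorization.

Each food is represented by its average iron, ascorbic-acid and phytate
content per 100 g serving.  Food-pattern modeling reduces every food to a
dichotomous "high" / "low" label per nutrient of interest by comparing the
per-100 g content against fixed cutoffs; the conventional values are
0.35 mg/100 g for iron, 24 mg/100 g for ascorbic acid, 50 mg/100 g for
phytate, and 1 for the phytate:iron ratio (the classical molar-ratio
threshold above which non-heme iron absorption is considered inhibited).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

#: g/mol, phytic acid (myo-inositol hexakisphosphate)
PHYTATE_MOLAR_MASS = 660.04
#: g/mol, elemental iron
IRON_MOLAR_MASS = 55.845

VARIABLES = ("iron", "ascorbic", "phytate", "ratio")

RatioMode = Literal["molar", "mass"]

COMPOSITION_COLUMNS = [
    "food_id",
    "name",
    "iron_mg_per_100g",
    "ascorbic_mg_per_100g",
    "phytate_mg_per_100g",
]


class InvalidInputError(ValueError):
    """Raised when a food record or table violates its invariants."""


@dataclass(frozen=True)
class FoodRecord:
    """One food with average nutrient content per 100 g serving."""

    food_id: str
    name: str
    iron_mg_per_100g: float
    ascorbic_mg_per_100g: float
    phytate_mg_per_100g: float

    def __post_init__(self) -> None:
        for attr in ("iron_mg_per_100g", "ascorbic_mg_per_100g", "phytate_mg_per_100g"):
            value = getattr(self, attr)
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(
                    f"food {self.food_id!r}: {attr}={value!r} must be finite and >= 0"
                )


@dataclass(frozen=True)
class CutoffTable:
    """High/low nutrient-density cutoffs (per 100 g) and the ratio convention.

    A food is "high" for a variable iff its value strictly exceeds the cutoff;
    a value exactly at the cutoff is "low".
    """

    iron_cutoff: float = 0.35
    ascorbic_cutoff: float = 24.0
    phytate_cutoff: float = 50.0
    ratio_cutoff: float = 1.0
    ratio_mode: RatioMode = "molar"

    def __post_init__(self) -> None:
        for attr in ("iron_cutoff", "ascorbic_cutoff", "phytate_cutoff", "ratio_cutoff"):
            if not getattr(self, attr) > 0:
                raise InvalidInputError(f"{attr} must be > 0")
        if self.ratio_mode not in ("molar", "mass"):
            raise InvalidInputError(f"ratio_mode must be 'molar' or 'mass', got {self.ratio_mode!r}")


@dataclass(frozen=True)
class CategoryLabels:
    """Per-variable high/low label for one food."""

    iron: Literal["high", "low"]
    ascorbic: Literal["high", "low"]
    phytate: Literal["high", "low"]
    ratio: Literal["high", "low"]

    labels: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "labels",
            {"iron": self.iron, "ascorbic": self.ascorbic, "phytate": self.phytate, "ratio": self.ratio},
        )


def food_ratio(food: FoodRecord, mode: RatioMode = "molar") -> float:
    """Per-food phytate:iron ratio on a per-100 g basis.

    ``molar`` divides millimoles of phytate by millimoles of iron; ``mass``
    divides milligrams by milligrams.  A food with phytate but no iron is
    maximally inhibitory (+inf); a food with neither is assigned 0.
    """
    phytate = food.phytate_mg_per_100g
    iron = food.iron_mg_per_100g
    if iron == 0:
        return math.inf if phytate > 0 else 0.0
    if mode == "molar":
        return (phytate / PHYTATE_MOLAR_MASS) / (iron / IRON_MOLAR_MASS)
    if mode == "mass":
        return phytate / iron
    raise InvalidInputError(f"unknown ratio mode {mode!r}")


def categorize_food(food: FoodRecord, cutoffs: CutoffTable | None = None) -> CategoryLabels:
    """Label a food high/low for each of the four variables of interest.

    "High" means strictly above the cutoff; a value exactly at the cutoff is
    "low".  The ratio variable compares the per-food phytate:iron ratio
    (in ``cutoffs.ratio_mode``) against ``cutoffs.ratio_cutoff``.
    """
    if cutoffs is None:
        cutoffs = CutoffTable()
    ratio = food_ratio(food, cutoffs.ratio_mode)

    def lab(value: float, cutoff: float) -> str:
        return "high" if value > cutoff else "low"

    return CategoryLabels(
        iron=lab(food.iron_mg_per_100g, cutoffs.iron_cutoff),
        ascorbic=lab(food.ascorbic_mg_per_100g, cutoffs.ascorbic_cutoff),
        phytate=lab(food.phytate_mg_per_100g, cutoffs.phytate_cutoff),
        ratio=lab(ratio, cutoffs.ratio_cutoff),
    )


def _validate_composition_frame(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COMPOSITION_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"composition table missing column(s): {missing}")
    table = table.copy()
    table["food_id"] = table["food_id"].astype(str)
    dup = table["food_id"][table["food_id"].duplicated()]
    if not dup.empty:
        raise InvalidInputError(f"duplicate food_id(s) in composition table: {sorted(set(dup))}")
    for col in COMPOSITION_COLUMNS[2:]:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[~np.isfinite(values) | (values < 0)]
        if len(bad):
            row = bad[0]
            raise InvalidInputError(
                f"composition table row {row} (food_id={table.loc[row, 'food_id']!r}): "
                f"{col}={table.loc[row, col]!r} must be finite and >= 0"
            )
        table[col] = values.astype(float)
    return table


def load_composition_table(path) -> pd.DataFrame:
    """Read a composition CSV (food_id,name,iron/ascorbic/phytate mg per 100 g).

    Returns a validated DataFrame with one row per food.  Duplicated food
    ids, missing columns and negative or non-finite values are rejected with
    an error naming the offending row.
    """
    return _validate_composition_frame(pd.read_csv(path))


def categorize_table(table: pd.DataFrame, cutoffs: CutoffTable | None = None) -> pd.DataFrame:
    """Vectorized high/low categorization of a whole composition table.

    Returns the table with four added boolean columns ``high_iron``,
    ``high_ascorbic``, ``high_phytate``, ``high_ratio`` plus the per-food
    ``ratio`` column used for the last label.
    """
    if cutoffs is None:
        cutoffs = CutoffTable()
    table = _validate_composition_frame(table)
    iron = table["iron_mg_per_100g"].to_numpy()
    phytate = table["phytate_mg_per_100g"].to_numpy()
    if cutoffs.ratio_mode == "molar":
        scale = IRON_MOLAR_MASS / PHYTATE_MOLAR_MASS
    else:
        scale = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            iron > 0,
            scale * phytate / np.where(iron > 0, iron, 1.0),
            np.where(phytate > 0, np.inf, 0.0),
        )
    table["ratio"] = ratio
    table["high_iron"] = iron > cutoffs.iron_cutoff
    table["high_ascorbic"] = table["ascorbic_mg_per_100g"].to_numpy() > cutoffs.ascorbic_cutoff
    table["high_phytate"] = phytate > cutoffs.phytate_cutoff
    table["high_ratio"] = ratio > cutoffs.ratio_cutoff
    return table


def records_to_frame(records: list[FoodRecord]) -> pd.DataFrame:
    """Build a composition DataFrame from FoodRecord objects."""
    return _validate_composition_frame(
        pd.DataFrame(
            [
                {
                    "food_id": r.food_id,
                    "name": r.name,
                    "iron_mg_per_100g": r.iron_mg_per_100g,
                    "ascorbic_mg_per_100g": r.ascorbic_mg_per_100g,
                    "phytate_mg_per_100g": r.phytate_mg_per_100g,
                }
                for r in records
            ]
        )
    )
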