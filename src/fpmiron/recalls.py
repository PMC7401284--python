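"""Turn item-level multi-day 24 h recall records into per-participant scores.

Two competing variable sets are derived for every participant:

* **MIE** (mean dietary intake estimates): daily iron, ascorbic-acid and
  phytate totals in mg summed over the items eaten each day and averaged
  across recall days, plus the participant-level phytate:iron ratio of the
  averaged intakes.
* **FPM** (food-pattern-modeling nutrient densities): for each variable, the
  fraction of consumed foods labeled "high" nutrient density, ignoring
  portion sizes entirely.

The recall CSV dialect is one row per eaten item:
``participant_id,day_index,food_id,grams_consumed``.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from fpmiron.composition import (
    IRON_MOLAR_MASS,
    PHYTATE_MOLAR_MASS,
    VARIABLES,
    CutoffTable,
    InvalidInputError,
    RatioMode,
    categorize_table,
)

logger = logging.getLogger(__name__)

RECALL_COLUMNS = ["participant_id", "day_index", "food_id", "grams_consumed"]

CountingMode = Literal["instances", "unique_foods"]

NUTRIENT_COLS = {
    "iron": "iron_mg_per_100g",
    "ascorbic": "ascorbic_mg_per_100g",
    "phytate": "phytate_mg_per_100g",
}


def load_recalls(path) -> pd.DataFrame:
    """Read and validate a recall-item CSV (one row per eaten item)."""
    recalls = pd.read_csv(path)
    return validate_recalls(recalls)


def validate_recalls(recalls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECALL_COLUMNS if c not in recalls.columns]
    if missing:
        raise InvalidInputError(f"recall table missing column(s): {missing}")
    recalls = recalls.copy()
    recalls["participant_id"] = recalls["participant_id"].astype(str)
    recalls["food_id"] = recalls["food_id"].astype(str)
    recalls["day_index"] = pd.to_numeric(recalls["day_index"], errors="coerce")
    if (recalls["day_index"] < 1).any() or recalls["day_index"].isna().any():
        raise InvalidInputError("day_index must be an integer >= 1")
    recalls["day_index"] = recalls["day_index"].astype(int)
    grams = pd.to_numeric(recalls["grams_consumed"], errors="coerce")
    bad = recalls.index[~np.isfinite(grams) | (grams <= 0)]
    if len(bad):
        row = bad[0]
        raise InvalidInputError(
            f"recall row {row}: grams_consumed={recalls.loc[row, 'grams_consumed']!r} "
            "must be finite and > 0"
        )
    recalls["grams_consumed"] = grams.astype(float)
    return recalls


def _resolve(recalls: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Left-join recall items onto the composition table, failing loudly on
    food ids that do not resolve."""
    merged = recalls.merge(table, on="food_id", how="left", validate="many_to_one")
    unresolved = merged[merged["iron_mg_per_100g"].isna()]
    if not unresolved.empty:
        first = unresolved.iloc[0]
        raise InvalidInputError(
            f"unresolvable food_id {first['food_id']!r} "
            f"(participant {first['participant_id']!r}, day {first['day_index']})"
        )
    return merged


def daily_intake(items: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day iron/ascorbic/phytate totals in mg.

    Each total is sum over items of grams_consumed x (mg per 100 g) / 100.
    Participant-days absent from ``items`` simply do not appear; an empty
    input yields an empty frame with a warning.
    """
    items = validate_recalls(items)
    if items.empty:
        logger.warning("daily_intake called with no recall items; totals are empty")
        return pd.DataFrame(
            columns=["participant_id", "day_index", "iron_mg", "ascorbic_mg", "phytate_mg"]
        )
    merged = _resolve(items, table)
    for var, col in NUTRIENT_COLS.items():
        merged[f"{var}_mg"] = merged["grams_consumed"] * merged[col] / 100.0
    out = (
        merged.groupby(["participant_id", "day_index"], as_index=False)[
            ["iron_mg", "ascorbic_mg", "phytate_mg"]
        ]
        .sum()
        .sort_values(["participant_id", "day_index"], ignore_index=True)
    )
    return out


def mean_intake(daily: pd.DataFrame, ratio_mode: RatioMode = "molar") -> pd.DataFrame:
    """Average daily totals across recall days -> MIE variables per participant.

    Adds ``mie_ratio``, the phytate:iron ratio of the averaged intakes (see
    :func:`participant_ratio`).
    """
    if daily.empty:
        raise InvalidInputError("mean_intake requires at least one recall day")
    grouped = daily.groupby("participant_id")
    out = grouped[["iron_mg", "ascorbic_mg", "phytate_mg"]].mean()
    out.columns = ["mie_iron", "mie_ascorbic", "mie_phytate"]
    out["n_days"] = grouped.size()
    out["mie_ratio"] = [
        participant_ratio(p, i, ratio_mode)
        for p, i in zip(out["mie_phytate"], out["mie_iron"])
    ]
    return out.reset_index()


def participant_ratio(
    mean_phytate_mg: float, mean_iron_mg: float, mode: RatioMode = "molar"
) -> float:
    """Participant-level phytate:iron ratio of mean daily intakes.

    ``molar`` converts both intakes to millimoles before dividing; ``mass``
    divides the mg amounts directly.  Zero mean iron intake makes the ratio
    undefined and raises.
    """
    if not (mean_iron_mg > 0):
        raise InvalidInputError(
            f"phytate:iron ratio undefined for mean iron intake {mean_iron_mg!r} mg"
        )
    if mode == "molar":
        return (mean_phytate_mg / PHYTATE_MOLAR_MASS) / (mean_iron_mg / IRON_MOLAR_MASS)
    if mode == "mass":
        return mean_phytate_mg / mean_iron_mg
    raise InvalidInputError(f"unknown ratio mode {mode!r}")


def fpm_density(
    items: pd.DataFrame,
    table: pd.DataFrame,
    cutoffs: CutoffTable | None = None,
    counting_mode: CountingMode = "instances",
) -> pd.DataFrame:
    """Food-pattern-modeling nutrient density per participant.

    For each variable, density = (# consumed foods labeled high) / (# foods
    consumed), a fraction in [0, 1].  ``instances`` counts every eaten item
    across all recall days (default); ``unique_foods`` deduplicates by
    food_id before counting.
    """
    items = validate_recalls(items)
    if items.empty:
        raise InvalidInputError("fpm_density requires at least one consumed food")
    labeled = categorize_table(table, cutoffs)
    merged = _resolve(items, labeled)
    if counting_mode == "unique_foods":
        merged = merged.drop_duplicates(["participant_id", "food_id"])
    elif counting_mode != "instances":
        raise InvalidInputError(f"unknown counting mode {counting_mode!r}")
    grouped = merged.groupby("participant_id")
    out = grouped[[f"high_{v}" for v in VARIABLES]].mean()
    out.columns = [f"fpm_{v}" for v in VARIABLES]
    out["n_foods_total"] = grouped.size()
    return out.reset_index()


def build_profiles(
    recalls: pd.DataFrame,
    table: pd.DataFrame,
    cutoffs: CutoffTable | None = None,
    required_days: int = 3,
    ratio_mode: RatioMode = "molar",
    counting_mode: CountingMode = "instances",
) -> pd.DataFrame:
    """Full per-participant profile table: MIE and FPM variables side by side.

    Participants with fewer than ``required_days`` completed recall days are
    excluded (with a logged count), mirroring the usual multi-day recall
    completeness requirement.  Raises if no participant survives the filter.
    """
    recalls = validate_recalls(recalls)
    if cutoffs is None:
        cutoffs = CutoffTable(ratio_mode=ratio_mode)
    else:
        # single global ratio convention: the cutoff table owns it
        ratio_mode = cutoffs.ratio_mode
    n_before = recalls["participant_id"].nunique()
    days_per_participant = recalls.groupby("participant_id")["day_index"].nunique()
    keep = days_per_participant.index[days_per_participant >= required_days]
    excluded = n_before - len(keep)
    if excluded:
        logger.info(
            "excluding %d of %d participants with fewer than %d recall days",
            excluded,
            n_before,
            required_days,
        )
    if not len(keep):
        raise InvalidInputError(
            f"no participants with >= {required_days} recall days (cohort of {n_before})"
        )
    recalls = recalls[recalls["participant_id"].isin(keep)]

    daily = daily_intake(recalls, table)
    mie = mean_intake(daily, ratio_mode=ratio_mode)
    fpm = fpm_density(recalls, table, cutoffs, counting_mode=counting_mode)
    profiles = mie.merge(fpm, on="participant_id", validate="one_to_one")
    return profiles.sort_values("participant_id", ignore_index=True)
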