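"""Multiple-traffic-light (MTL) front-of-package classification.

Each item gets a green/amber/red light for fat, saturated fat, total sugar
and salt from its content per 100 g (drinks use the lower drink cut-offs,
100 ml taken as 100 g). An item with no red light is "healthy"; one or
more red lights makes it "unhealthy". Band boundaries belong to the lower
band: a value exactly at a cut-off keeps the lower colour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FOPL_NUTRIENTS,
    FoodItem,
    MTLThresholdSet,
    salt_column,
    salt_from_sodium,
)

GREEN, AMBER, RED = "green", "amber", "red"
COLOUR_ORDER = {GREEN: 0, AMBER: 1, RED: 2}


@dataclass(frozen=True)
class FOPLResult:
    """Traffic-light colours for one item plus the derived healthy flag."""

    fat: str
    satfat: str
    sugar: str
    salt: str

    @property
    def colours(self) -> dict[str, str]:
        return {"fat": self.fat, "satfat": self.satfat, "sugar": self.sugar, "salt": self.salt}

    @property
    def n_red(self) -> int:
        return sum(c == RED for c in self.colours.values())

    @property
    def healthy(self) -> bool:
        """Healthy iff no nutrient is red."""
        return self.n_red == 0


def classify_nutrient(
    value_g_100g: float, nutrient: str, is_drink: bool, thresholds: MTLThresholdSet
) -> str:
    """Colour for one nutrient value (g/100 g) under the applicable dialect."""
    if value_g_100g < 0:
        raise ValueError(f"{nutrient} value must be non-negative, got {value_g_100g}")
    cut = thresholds.cut(nutrient, is_drink)
    if value_g_100g <= cut.amber:
        return GREEN
    if value_g_100g <= cut.red:
        return AMBER
    return RED


def classify_item(item: FoodItem, thresholds: MTLThresholdSet) -> FOPLResult:
    """Classify all four FOPL nutrients of one item; salt derives from sodium."""
    values = {
        "fat": item.fat_g_100g,
        "satfat": item.satfat_g_100g,
        "sugar": item.sugar_g_100g,
        "salt": salt_from_sodium(item.sodium_mg_100g),
    }
    for nutrient, v in values.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"item {item.item_id}: missing FOPL nutrient {nutrient}")
    return FOPLResult(
        **{
            n: classify_nutrient(values[n], n, item.is_drink, thresholds)
            for n in FOPL_NUTRIENTS
        }
    )


def classify_table(items: pd.DataFrame, thresholds: MTLThresholdSet) -> pd.DataFrame:
    """Vectorised classification of an item table.

    Returns a frame indexed like ``items`` with one colour column per FOPL
    nutrient plus ``n_red`` and ``healthy``.
    """
    values = {
        "fat": items["fat_g_100g"].to_numpy(float),
        "satfat": items["satfat_g_100g"].to_numpy(float),
        "sugar": items["sugar_g_100g"].to_numpy(float),
        "salt": salt_column(items).to_numpy(float),
    }
    is_drink = items["is_drink"].to_numpy(bool)
    out = pd.DataFrame(index=items.index)
    for nutrient, v in values.items():
        if np.any(np.isnan(v)):
            bad = items.loc[np.isnan(v), "item_id"].tolist()
            raise ValueError(f"missing FOPL nutrient {nutrient} for items {bad[:5]}")
        if np.any(v < 0):
            raise ValueError(f"negative {nutrient} values in table")
        colour = np.full(len(items), GREEN, dtype=object)
        for drink in (False, True):
            cut = thresholds.cut(nutrient, drink)
            sel = is_drink == drink
            colour[sel & (v > cut.amber)] = AMBER
            colour[sel & (v > cut.red)] = RED
        out[f"fopl_{nutrient}"] = colour
    out["n_red"] = (out[[f"fopl_{n}" for n in FOPL_NUTRIENTS]] == RED).sum(axis=1)
    out["healthy"] = out["n_red"] == 0
    return out
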