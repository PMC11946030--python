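"""% RNI contributions, composite scores and attainment counters.

An item's contribution to a micronutrient recommendation is its content on
the chosen basis (per 100 g, or per 100 kcal for items with non-zero
energy) divided by the daily RNI, times 100. Contributions are not capped
at 100%. The composite score is the unweighted arithmetic mean of the
contributions over a membership set: 18 micronutrients for the headline
score (sodium, chloride and vitamin E excluded) or 20 for the sensitivity
variant (sodium and chloride included). An item missing any member of the
set has a missing composite but keeps its per-nutrient contributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import FoodItem, RNITable
from .registry import MicronutrientKey

BASES = ("per100g", "per100kcal")


class ZeroEnergyExclusion(ValueError):
    """Raised when a per-100 kcal quantity is requested for a zero-energy item."""


@dataclass(frozen=True)
class ContributionProfile:
    """Per-item % RNI contributions on one basis, plus composite scores."""

    item_id: str
    basis: str
    contrib: Mapping[MicronutrientKey, float]
    composite18: float | None
    composite20: float | None
    excluded_zero_energy: bool = False
    missing: frozenset[MicronutrientKey] = field(default_factory=frozenset)


def per_100kcal_density(item: FoodItem) -> dict[MicronutrientKey, float] | None:
    """Micronutrient content per 100 kcal, or None for zero-energy items.

    content/100 kcal = content/100 g x 100 / energy (kcal/100 g). Items
    with energy exactly 0 (water, weak tea, salt, no-calorie sweeteners)
    have no per-100 kcal representation and are excluded from that basis.
    """
    if item.energy_kcal_100g == 0:
        return None
    scale = 100.0 / item.energy_kcal_100g
    return {k: v * scale for k, v in item.micronutrients.items() if not math.isnan(v)}


def composite(
    contrib: Mapping[MicronutrientKey, float], key_set: frozenset[MicronutrientKey]
) -> float | None:
    """Unweighted mean contribution over ``key_set``; None if any member missing."""
    if not key_set:
        raise ValueError("empty composite key set")
    values = []
    for k in key_set:
        v = contrib.get(k)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        values.append(v)
    return float(np.mean(values))


def contribution(item: FoodItem, rni_table: RNITable, basis: str) -> ContributionProfile:
    """% RNI contribution profile of one item on the requested basis."""
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}, got {basis!r}")
    if basis == "per100kcal":
        amounts = per_100kcal_density(item)
        if amounts is None:
            raise ZeroEnergyExclusion(
                f"item {item.item_id} has zero energy; no per-100 kcal profile"
            )
    else:
        amounts = {k: v for k, v in item.micronutrients.items() if not math.isnan(v)}
    contrib = {
        k: 100.0 * amounts[k] / rni for k, rni in rni_table.rni.items() if k in amounts
    }
    missing = frozenset(k for k in rni_table.rni if k not in amounts)
    return ContributionProfile(
        item_id=item.item_id,
        basis=basis,
        contrib=contrib,
        composite18=composite(contrib, rni_table.composite18),
        composite20=composite(contrib, rni_table.composite20),
        missing=missing,
    )


def contribution_table(
    items: pd.DataFrame, rni_table: RNITable, basis: str
) -> pd.DataFrame:
    """Vectorised contribution profiles for a whole item table.

    Returns a frame indexed like ``items`` with one ``pct_<nutrient>``
    column per RNI-bearing micronutrient, ``composite18``/``composite20``
    columns, and an ``excluded_zero_energy`` flag. On the per-100 kcal
    basis, zero-energy rows are flagged and left entirely missing rather
    than silently zeroed.
    """
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}, got {basis!r}")
    energy = items["energy_kcal_100g"].to_numpy(float)
    excluded = np.zeros(len(items), dtype=bool)
    if basis == "per100kcal":
        excluded = energy == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(excluded, np.nan, 100.0 / energy)
    else:
        scale = np.ones(len(items))
    out = pd.DataFrame(index=items.index)
    for k, rni in rni_table.rni.items():
        col = k.column
        amount = (
            items[col].to_numpy(float) if col in items.columns else np.full(len(items), np.nan)
        )
        out[f"pct_{k.name}"] = 100.0 * amount * scale / rni
    c18 = [f"pct_{k.name}" for k in sorted(rni_table.composite18, key=lambda k: k.name)]
    c20 = [f"pct_{k.name}" for k in sorted(rni_table.composite20, key=lambda k: k.name)]
    # mean over the full set, NaN as soon as any member is missing
    out["composite18"] = out[c18].mean(axis=1).where(~out[c18].isna().any(axis=1))
    out["composite20"] = out[c20].mean(axis=1).where(~out[c20].isna().any(axis=1))
    out["excluded_zero_energy"] = excluded
    return out


def zero_content_proportions(
    items: pd.DataFrame, key: MicronutrientKey, group_col: str = "nova"
) -> pd.Series:
    """Proportion of non-missing values exactly zero, per group and overall."""
    col = key.column
    if col not in items.columns:
        raise KeyError(f"item table has no column for {key.name}")
    values = items[col].astype(float)
    present = values.notna()

    def prop(mask: pd.Series) -> float:
        n = int((present & mask).sum())
        return float(((values == 0) & mask).sum() / n) if n else float("nan")

    result = {
        g: prop(items[group_col] == g) for g in items[group_col].dropna().unique()
    }
    result["overall"] = prop(pd.Series(True, index=items.index))
    return pd.Series(result, name=f"zero_{key.name}")


@dataclass(frozen=True)
class AttainmentResult:
    """RNIs a diet of ``kcal_target`` kcal would meet at 100% and 80% of RNI."""

    kcal_target: float
    attained: frozenset[MicronutrientKey]
    attained_80: frozenset[MicronutrientKey]

    @property
    def count(self) -> int:
        return len(self.attained)

    @property
    def count_80(self) -> int:
        return len(self.attained_80)


def diet_attainment(
    median_contrib_per_100kcal: Mapping[MicronutrientKey, float],
    kcal_target: float,
    rni_keys: frozenset[MicronutrientKey] | None = None,
) -> AttainmentResult:
    """Scale per-100 kcal median contributions to a daily energy target.

    A micronutrient is attained when median %RNI/100 kcal x kcal_target/100
    reaches 100% (the 80% set is also reported). Keys default to those
    present in the input map.
    """
    if not kcal_target > 0:
        raise ValueError(f"kcal_target must be positive, got {kcal_target}")
    keys = rni_keys if rni_keys is not None else frozenset(median_contrib_per_100kcal)
    scale = kcal_target / 100.0
    scaled = {
        k: median_contrib_per_100kcal[k] * scale
        for k in keys
        if k in median_contrib_per_100kcal
        and not math.isnan(median_contrib_per_100kcal[k])
    }
    return AttainmentResult(
        kcal_target=kcal_target,
        attained=frozenset(k for k, v in scaled.items() if v >= 100.0),
        attained_80=frozenset(k for k, v in scaled.items() if v >= 80.0),
    )


def count_recommendations_met(
    daily_intake: Mapping[MicronutrientKey, float], rni_table: RNITable
) -> int:
    """Number of composite-18 recommendations met by a daily intake vector.

    A missing intake entry counts as not met, with a warning.
    """
    met = 0
    for k in rni_table.composite18:
        v = daily_intake.get(k)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            warnings.warn(f"intake missing for {k.name}; counted as not met")
            continue
        if v >= rni_table.rni[k]:
            met += 1
    return met
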