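"""Domain types, unit conventions, RNI registry and validation.

Everything downstream (traffic-light classification, % RNI scoring, group
statistics) works on the types defined here. Quantities are stored per
100 g of item in the canonical unit fixed by :mod:`micronova.registry`;
reference nutrient intakes (RNIs) are per day in the same units. Missing
values are genuinely missing (NaN / absent), never zero: the analysis
distinguishes "zero content" (a reportable fact about an item) from
"no data" (an item excluded from composite scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import registry
from .registry import COMPOSITE18, COMPOSITE20, MicronutrientKey

NOVA_GROUPS = ("MPF", "PCI", "PF", "UPF")

#: Conversion from sodium to salt equivalent: salt (g) = Na (mg) x 2.5 / 1000.
SODIUM_TO_SALT = 2.5 / 1000.0

FOPL_NUTRIENTS = ("fat", "satfat", "sugar", "salt")

# Canonical column names for the delimited item-table format.
ID_COLUMNS = ["item_id", "name", "nova", "is_drink"]
MACRO_COLUMNS = [
    "energy_kcal_100g",
    "fat_g_100g",
    "satfat_g_100g",
    "sugar_g_100g",
    "sodium_mg_100g",
]
MICRO_COLUMNS = [k.column for k in registry.ALL_KEYS]
# sodium is both a FOPL macro input and an RNI-bearing micronutrient; its
# single column serves both roles, so deduplicate while preserving order.
ALL_COLUMNS = list(dict.fromkeys(ID_COLUMNS + MACRO_COLUMNS + MICRO_COLUMNS))


class ConfigError(ValueError):
    """A configuration file is missing, malformed or inconsistent."""


@dataclass(frozen=True)
class FoodItem:
    """One nutrient-databank row: identity, Nova label and densities per 100 g."""

    item_id: str
    name: str
    nova: str
    is_drink: bool
    energy_kcal_100g: float
    fat_g_100g: float
    satfat_g_100g: float
    sugar_g_100g: float
    sodium_mg_100g: float
    micronutrients: Mapping[MicronutrientKey, float] = field(default_factory=dict)

    def micronutrient(self, key: MicronutrientKey) -> float | None:
        """Content of ``key`` per 100 g, or None when missing."""
        v = self.micronutrients.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v


@dataclass(frozen=True)
class RNITable:
    """Per-sex reference nutrient intakes plus composite membership sets."""

    sex: str
    rni: Mapping[MicronutrientKey, float]
    composite18: frozenset[MicronutrientKey] = COMPOSITE18
    composite20: frozenset[MicronutrientKey] = COMPOSITE20

    def __post_init__(self) -> None:
        missing = sorted(k.name for k in self.composite20 if k not in self.rni)
        if missing:
            raise ConfigError(f"RNI missing for composite micronutrient(s): {missing}")
        bad = sorted(k.name for k, v in self.rni.items() if not v > 0)
        if bad:
            raise ConfigError(f"non-positive RNI for: {bad}")


@dataclass(frozen=True)
class NutrientCut:
    """Green/amber and amber/red cut-offs for one nutrient, g per 100 g."""

    amber: float
    red: float

    def __post_init__(self) -> None:
        if not (0 < self.amber < self.red):
            raise ConfigError(
                f"cut-offs must satisfy 0 < amber < red, got {self.amber}, {self.red}"
            )


@dataclass(frozen=True)
class MTLThresholdSet:
    """MTL cut-offs per nutrient for the food and drink dialects."""

    food: Mapping[str, NutrientCut]
    drink: Mapping[str, NutrientCut]

    def __post_init__(self) -> None:
        for dialect in (self.food, self.drink):
            missing = set(FOPL_NUTRIENTS) - set(dialect)
            if missing:
                raise ConfigError(f"thresholds missing nutrients: {sorted(missing)}")

    def cut(self, nutrient: str, is_drink: bool) -> NutrientCut:
        if nutrient not in FOPL_NUTRIENTS:
            raise KeyError(f"unknown FOPL nutrient {nutrient!r}")
        return (self.drink if is_drink else self.food)[nutrient]


def _default_path(name: str) -> Path:
    return Path(str(resources.files("micronova").joinpath("data").joinpath(name)))


def default_rni_path(sex: str) -> Path:
    if sex not in ("female", "male"):
        raise ConfigError(f"sex must be 'female' or 'male', got {sex!r}")
    return _default_path(f"rni_{sex}.yaml")


def default_threshold_path() -> Path:
    return _default_path("mtl_thresholds.yaml")


def load_rni_table(config_path: str | Path | None = None, sex: str = "female") -> RNITable:
    """Load and validate an RNI table.

    With no path, the packaged UK government defaults for the requested sex
    are used. Unknown micronutrient names, missing composite members and
    non-positive values are rejected with errors naming the offender.
    """
    path = Path(config_path) if config_path is not None else default_rni_path(sex)
    if not path.exists():
        raise ConfigError(f"RNI config not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "rni" not in raw:
        raise ConfigError(f"RNI config {path} must be a mapping with an 'rni' section")
    file_sex = raw.get("sex", sex)
    rni: dict[MicronutrientKey, float] = {}
    for name, entry in raw["rni"].items():
        try:
            k = registry.key(name)
        except KeyError as e:
            raise ConfigError(str(e)) from None
        if isinstance(entry, Mapping):
            value, unit = entry.get("value"), entry.get("unit")
        else:
            value, unit = entry, k.unit
        if unit != k.unit:
            raise ConfigError(
                f"RNI for {name!r} given in {unit!r}; canonical unit is {k.unit!r}"
            )
        value = float(value)
        if not value > 0:
            raise ConfigError(f"RNI for {name!r} must be positive, got {value}")
        rni[k] = value
    return RNITable(sex=file_sex, rni=rni)


def load_thresholds(config_path: str | Path | None = None) -> MTLThresholdSet:
    """Load MTL cut-offs; defaults to the packaged FSA guidance values."""
    path = Path(config_path) if config_path is not None else default_threshold_path()
    if not path.exists():
        raise ConfigError(f"threshold config not found: {path}")
    raw = yaml.safe_load(path.read_text())
    out: dict[str, dict[str, NutrientCut]] = {}
    for dialect in ("food", "drink"):
        if dialect not in raw:
            raise ConfigError(f"threshold config missing {dialect!r} section")
        out[dialect] = {
            nutrient: NutrientCut(float(c["amber"]), float(c["red"]))
            for nutrient, c in raw[dialect].items()
        }
    return MTLThresholdSet(food=out["food"], drink=out["drink"])


def salt_from_sodium(sodium_mg_100g: float) -> float:
    """Salt equivalent (g/100 g) from sodium (mg/100 g): Na x 2.5 / 1000."""
    if sodium_mg_100g < 0:
        raise ValueError(f"sodium must be non-negative, got {sodium_mg_100g}")
    return sodium_mg_100g * SODIUM_TO_SALT


@dataclass(frozen=True)
class ValidationIssue:
    row: object  # item_id or positional index
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, {self.field}: {self.message}"


def validate_items(items: pd.DataFrame) -> list[ValidationIssue]:
    """Collect per-row problems in an item table without raising.

    Checks: required columns present, Nova labels among the four groups,
    numeric fields non-negative where present (NaN means missing and is
    allowed), no unknown nutrient columns.
    """
    issues: list[ValidationIssue] = []
    known = set(ALL_COLUMNS)
    for col in items.columns:
        if col not in known:
            issues.append(ValidationIssue("-", col, "unknown column"))
    for col in ID_COLUMNS + ["energy_kcal_100g"]:
        if col not in items.columns:
            issues.append(ValidationIssue("-", col, "required column missing"))
            return issues
    ids = items["item_id"]
    bad_nova = ~items["nova"].isin(NOVA_GROUPS)
    for rid, label in zip(ids[bad_nova], items.loc[bad_nova, "nova"]):
        issues.append(ValidationIssue(rid, "nova", f"unknown Nova label {label!r}"))
    numeric = [c for c in MACRO_COLUMNS + MICRO_COLUMNS if c in items.columns]
    for col in numeric:
        neg = items[col] < 0  # NaN compares False: missing is allowed here
        for rid, v in zip(ids[neg], items.loc[neg, col]):
            issues.append(ValidationIssue(rid, col, f"negative value {v}"))
    return issues


def read_item_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited item table; empty cells stay NaN (missing, not zero)."""
    df = pd.read_csv(
        path,
        dtype={"item_id": str, "name": str, "nova": str},
        float_precision="round_trip",  # decimal text must survive a round trip
    )
    if "is_drink" in df.columns:
        df["is_drink"] = df["is_drink"].astype(bool)
    return df


def write_item_table(items: pd.DataFrame, path: str | Path) -> None:
    """Write an item table as comma-delimited UTF-8 text; NaN becomes empty."""
    items.to_csv(path, index=False)


def items_from_frame(items: pd.DataFrame) -> list[FoodItem]:
    """Materialise FoodItem objects from a validated table."""
    out: list[FoodItem] = []
    for row in items.itertuples(index=False):
        micro = {}
        for k in registry.ALL_KEYS:
            if k.column in items.columns:
                v = getattr(row, k.column)
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    micro[k] = float(v)
        out.append(
            FoodItem(
                item_id=str(row.item_id),
                name=str(row.name),
                nova=str(row.nova),
                is_drink=bool(row.is_drink),
                energy_kcal_100g=float(row.energy_kcal_100g),
                fat_g_100g=float(row.fat_g_100g),
                satfat_g_100g=float(row.satfat_g_100g),
                sugar_g_100g=float(row.sugar_g_100g),
                sodium_mg_100g=float(row.sodium_mg_100g),
                micronutrients=micro,
            )
        )
    return out


def salt_column(items: pd.DataFrame) -> pd.Series:
    """Salt g/100 g for every row: an explicit salt column wins, else from Na."""
    if "salt_g_100g" in items.columns:
        return items["salt_g_100g"].astype(float)
    return items["sodium_mg_100g"].astype(float) * SODIUM_TO_SALT


def check_items(items: pd.DataFrame) -> Iterable[str]:
    """Convenience: stringified validation issues."""
    return [str(i) for i in validate_items(items)]
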