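"""Canonical micronutrient registry.

Every micronutrient carried by an NDNS-style nutrient databank is registered
here once, with a canonical unit, so that all I/O and arithmetic share a
single authority and quantities never silently change unit. Twenty of the
keys carry a UK reference nutrient intake (RNI); the rest (vitamin E,
pantothenic acid, biotin, manganese, retinol, the carotene fractions and the
haem/non-haem iron split) are tracked as absolute content only and never
enter % RNI contributions.

Composite membership:

* ``COMPOSITE18`` — the 18 RNI-bearing micronutrients averaged into the
  headline composite score: all RNI keys except sodium and chloride
  (sodium is a nutrient to limit; chloride is consumed almost entirely as
  sodium chloride). Vitamin E has no UK government RNI and is never a
  member.
* ``COMPOSITE20`` — the sensitivity composite: the same set plus sodium and
  chloride.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MicronutrientKey:
    """A canonical micronutrient: name plus the unit all values are stored in."""

    name: str
    unit: str  # per 100 g of item, or per day for an RNI

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} ({self.unit}/100g)"

    @property
    def column(self) -> str:
        """Column name used in delimited item tables, e.g. ``vitamin_c_mg_100g``."""
        return f"{self.name}_{self.unit}_100g"


def _k(name: str, unit: str) -> MicronutrientKey:
    return MicronutrientKey(name, unit)


# The 20 RNI-bearing micronutrients (vitamin A is expressed as retinol
# equivalents; niacin as niacin equivalents).
RNI_KEYS: tuple[MicronutrientKey, ...] = (
    _k("vitamin_a", "ug"),
    _k("vitamin_d", "ug"),
    _k("vitamin_c", "mg"),
    _k("thiamin", "mg"),
    _k("riboflavin", "mg"),
    _k("niacin_equivalent", "mg"),
    _k("vitamin_b6", "mg"),
    _k("vitamin_b12", "ug"),
    _k("folate", "ug"),
    _k("potassium", "mg"),
    _k("calcium", "mg"),
    _k("magnesium", "mg"),
    _k("phosphorus", "mg"),
    _k("iron", "mg"),
    _k("copper", "mg"),
    _k("zinc", "mg"),
    _k("sodium", "mg"),
    _k("chloride", "mg"),
    _k("iodine", "ug"),
    _k("selenium", "ug"),
)

# Tracked but without a UK government RNI; excluded from all composites.
NON_RNI_KEYS: tuple[MicronutrientKey, ...] = (
    _k("vitamin_e", "mg"),
    _k("pantothenic_acid", "mg"),
    _k("biotin", "ug"),
    _k("manganese", "mg"),
    _k("retinol", "ug"),
    _k("total_carotene", "ug"),
    _k("alpha_carotene", "ug"),
    _k("beta_carotene", "ug"),
    _k("beta_cryptoxanthin", "ug"),
    _k("haem_iron", "mg"),
    _k("non_haem_iron", "mg"),
)

ALL_KEYS: tuple[MicronutrientKey, ...] = RNI_KEYS + NON_RNI_KEYS

BY_NAME: dict[str, MicronutrientKey] = {k.name: k for k in ALL_KEYS}

SODIUM = BY_NAME["sodium"]
CHLORIDE = BY_NAME["chloride"]

COMPOSITE20: frozenset[MicronutrientKey] = frozenset(RNI_KEYS)
COMPOSITE18: frozenset[MicronutrientKey] = COMPOSITE20 - {SODIUM, CHLORIDE}


def key(name: str) -> MicronutrientKey:
    """Look up a registered key by canonical name; unknown names raise KeyError."""
    try:
        return BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown micronutrient {name!r}; registered keys: {sorted(BY_NAME)}"
        ) from None
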