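"""Synthetic NDNS-like nutrient databank generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without the UK Data Service databank download:

* Nova-group sizes and per-group composite micronutrient densities
  (% RNI per 100 kcal) with log-normal spread calibrated from reported
  medians and IQRs; the per-item composite score is drawn directly and
  split across the 18 composite micronutrients with a Dirichlet weight
  vector, so group composite medians hit their targets by construction.
* Macronutrient (fat, saturated fat, sugar, salt) distributions drawn from
  log-normals calibrated so that the probability of exceeding the red
  traffic-light cut-off equals the configured per-group rate, with a
  shared latent "unhealthiness" factor per item that couples red lights,
  energy density and (negatively) micronutrient density — reproducing the
  direction effects of real retail food data.
* Energy density built as 9 x fat + 4 x sugar + a log-normal remainder,
  drinks lighter than foods; a configurable number of zero-energy items
  (water / weak tea / salt / sweetener templates); per-nutrient
  zero-content inflation; and missing selenium injected into a configured
  number of UPF rows.

Everything is reproducible from (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import registry
from .core import (
    ALL_COLUMNS,
    NOVA_GROUPS,
    MTLThresholdSet,
    RNITable,
    load_rni_table,
    load_thresholds,
)
from .fopl import classify_table
from .scoring import contribution_table

MACROS = ("fat", "satfat", "sugar", "salt")
#: Composite-18 membership in fixed order (row layout of the weight matrix).
C18_KEYS = tuple(sorted(registry.COMPOSITE18, key=lambda k: k.name))
_POTASSIUM_IDX = [k.name for k in C18_KEYS].index("potassium")
#: Mass ratio Cl:Na in sodium chloride, used to derive chloride content.
CL_PER_NA = 35.45 / 22.99


@dataclass(frozen=True)
class GroupParams:
    n: int
    composite_median_100kcal: float
    composite_log_sigma: float
    drink_fraction: float
    red_light_prob: Mapping[str, float]
    energy_remainder_median: Mapping[str, float]
    zero_prob_multiplier: float = 1.0
    zero_energy: int = 0

    def validate(self, name: str) -> None:
        if self.n < 0 or self.zero_energy < 0 or self.zero_energy > self.n:
            raise ValueError(f"{name}: invalid counts n={self.n}, zero_energy={self.zero_energy}")
        if not self.composite_median_100kcal >= 0:
            raise ValueError(f"{name}: composite median must be >= 0")
        if not self.composite_log_sigma >= 0:
            raise ValueError(f"{name}: log-sigma must be >= 0")
        if not 0 <= self.drink_fraction <= 1:
            raise ValueError(f"{name}: drink fraction outside [0, 1]")
        for m in MACROS:
            p = self.red_light_prob.get(m)
            if p is None or not 0 <= p < 1:
                raise ValueError(
                    f"{name}: red-light probability for {m} must be in [0, 1); "
                    f"p = 1 is infeasible for a finite cut-off (got {p})"
                )


@dataclass(frozen=True)
class GeneratorParams:
    groups: Mapping[str, GroupParams]
    macro_log_sigma: Mapping[str, float]
    energy_log_sigma: float
    latent_macro_rho: float
    latent_energy_rho: float
    latent_micronutrient_rho: float
    dirichlet_concentration: float
    zero_content_prob: Mapping[str, float]
    missing_selenium_upf: int = 2
    n_non_nova: int = 0
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        for name, g in self.groups.items():
            if name not in NOVA_GROUPS:
                raise ValueError(f"unknown Nova group {name!r}")
            g.validate(name)
        for m in MACROS:
            if not self.macro_log_sigma.get(m, 0) > 0:
                raise ValueError(f"macro log-sigma for {m} must be positive")
        if not self.energy_log_sigma > 0 or not self.dirichlet_concentration > 0:
            raise ValueError("scale parameters must be positive")
        for rho in (self.latent_macro_rho, self.latent_energy_rho, self.latent_micronutrient_rho):
            if not -1 <= rho <= 1:
                raise ValueError("latent correlations must be in [-1, 1]")
        if min(self.missing_selenium_upf, self.n_non_nova, self.n_unmatched) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_items(self) -> int:
        return sum(g.n for g in self.groups.values())


def default_params_path() -> Path:
    return Path(str(resources.files("micronova").joinpath("data").joinpath("generator_defaults.yaml")))


def load_generator_params(config_path: str | Path | None = None, **overrides) -> GeneratorParams:
    """Load generator parameters; defaults are the packaged study conditions."""
    path = Path(config_path) if config_path is not None else default_params_path()
    raw = yaml.safe_load(path.read_text())
    shared = dict(raw["shared"])
    shared.update(overrides)
    groups = {
        name: GroupParams(
            n=int(g["n"]),
            composite_median_100kcal=float(g["composite_median_100kcal"]),
            composite_log_sigma=float(g["composite_log_sigma"]),
            drink_fraction=float(g["drink_fraction"]),
            red_light_prob={m: float(v) for m, v in g["red_light_prob"].items()},
            energy_remainder_median={d: float(v) for d, v in g["energy_remainder_median"].items()},
            zero_prob_multiplier=float(g.get("zero_prob_multiplier", 1.0)),
            zero_energy=int(g.get("zero_energy", 0)),
        )
        for name, g in raw["groups"].items()
    }
    return GeneratorParams(
        groups=groups,
        macro_log_sigma={m: float(v) for m, v in shared["macro_log_sigma"].items()},
        energy_log_sigma=float(shared["energy_log_sigma"]),
        latent_macro_rho=float(shared["latent_macro_rho"]),
        latent_energy_rho=float(shared["latent_energy_rho"]),
        latent_micronutrient_rho=float(shared["latent_micronutrient_rho"]),
        dirichlet_concentration=float(shared["dirichlet_concentration"]),
        zero_content_prob={k: float(v) for k, v in shared["zero_content_prob"].items()},
        missing_selenium_upf=int(shared.get("missing_selenium_upf", 2)),
        n_non_nova=int(shared.get("n_non_nova", 0)),
        n_unmatched=int(shared.get("n_unmatched", 0)),
    )


def _calibrated_lognormal(
    rng: np.random.Generator, cut: np.ndarray, sigma: float, p_exceed: float,
    shock: np.ndarray,
) -> np.ndarray:
    """Log-normal draws with P(X > cut) = p_exceed, given N(0,1) ``shock``.

    mu = ln(cut) - sigma * z_(1-p); p = 0 pushes the location four sigmas
    below the cut (exceedance ~ 3e-5).
    """
    z = 4.0 if p_exceed <= 0 else float(sps.norm.ppf(1.0 - p_exceed))
    mu = np.log(cut) - sigma * z
    return np.exp(mu + sigma * shock)


def _zero_energy_template(group: str) -> tuple[str, bool, float]:
    """(name stem, is_drink, sodium mg/100 g) for zero-energy rows."""
    if group == "PCI":
        return "salt", False, 38_000.0
    if group == "MPF":
        return "water/weak tea", True, 0.0
    return "no-calorie sweetener", False, 0.0


def generate_items(
    params: GeneratorParams | None = None,
    seed: int = 0,
    rni_table: RNITable | None = None,
    thresholds: MTLThresholdSet | None = None,
) -> pd.DataFrame:
    """Generate a synthetic item table (one row per item, canonical columns).

    ``rni_table`` anchors the % RNI densities back to absolute content per
    100 g (defaults to the packaged female table); ``thresholds`` supplies
    the red cut-offs the macronutrient draws are calibrated against.
    """
    params = params if params is not None else load_generator_params()
    rni_table = rni_table if rni_table is not None else load_rni_table(sex="female")
    thresholds = thresholds if thresholds is not None else load_thresholds()
    rng = np.random.default_rng(seed)

    frames = []
    for group in NOVA_GROUPS:  # fixed order: row layout never depends on dict order
        if group not in params.groups:
            continue
        frames.append(_generate_group(group, params, rng, rni_table, thresholds))
    df = pd.concat(frames, ignore_index=True)

    # missing-selenium injection among non-zero-energy UPF rows
    if params.missing_selenium_upf:
        se_col = registry.key("selenium").column
        upf_rows = df.index[(df["nova"] == "UPF") & (df["energy_kcal_100g"] > 0)]
        if len(upf_rows) < params.missing_selenium_upf:
            raise ValueError("not enough UPF rows for the requested selenium missingness")
        chosen = rng.choice(upf_rows, size=params.missing_selenium_upf, replace=False)
        df.loc[chosen, se_col] = np.nan

    extra = []
    for i in range(params.n_non_nova):
        extra.append(_blank_row(f"XN-{i:04d}", f"supplement {i} (non-Nova)", "NON_NOVA"))
    for i in range(params.n_unmatched):
        extra.append(_blank_row(f"XU-{i:04d}", f"unmatched item {i}", "MPF", matched=False))
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df[ALL_COLUMNS]


def _blank_row(item_id: str, name: str, nova: str, matched: bool = True) -> dict:
    row = dict.fromkeys(ALL_COLUMNS, np.nan)
    row.update(item_id=item_id, name=name, nova=nova, is_drink=False)
    if matched:
        row.update(
            energy_kcal_100g=100.0, fat_g_100g=1.0, satfat_g_100g=0.2,
            sugar_g_100g=1.0, sodium_mg_100g=50.0,
        )
    return row


def _generate_group(
    group: str,
    params: GeneratorParams,
    rng: np.random.Generator,
    rni_table: RNITable,
    thresholds: MTLThresholdSet,
) -> pd.DataFrame:
    gp = params.groups[group]
    n = gp.n
    is_drink = rng.random(n) < gp.drink_fraction
    u = rng.standard_normal(n)  # latent unhealthiness

    rho_m = params.latent_macro_rho
    macros = {}
    for m in MACROS:
        cut = np.where(
            is_drink, thresholds.cut(m, True).red, thresholds.cut(m, False).red
        )
        shock = rho_m * u + math.sqrt(1 - rho_m**2) * rng.standard_normal(n)
        macros[m] = _calibrated_lognormal(
            rng, cut, params.macro_log_sigma[m], gp.red_light_prob[m], shock
        )
    # physical consistency: total fat can never be below saturated fat
    macros["fat"] = np.maximum(macros["fat"], macros["satfat"])
    sodium = macros["salt"] * 400.0  # salt g -> Na mg

    rho_e = params.latent_energy_rho
    rem_med = np.where(
        is_drink,
        gp.energy_remainder_median.get("drink", 30.0),
        gp.energy_remainder_median["food"],
    )
    shock_e = rho_e * u + math.sqrt(1 - rho_e**2) * rng.standard_normal(n)
    remainder = rem_med * np.exp(params.energy_log_sigma * shock_e)
    energy = 9.0 * macros["fat"] + 4.0 * macros["sugar"] + remainder

    # composite %RNI per 100 kcal: log-normal with median = group target,
    # negatively coupled to the latent unhealthiness factor
    lam = params.latent_micronutrient_rho
    shock_c = lam * u + math.sqrt(1 - lam**2) * rng.standard_normal(n)
    # stratified latent draw: replace the iid shocks by the exact normal
    # quantiles in the same rank order. The composite distribution and its
    # coupling to the latent factor are unchanged, but the realised group
    # median is pinned at the configured target instead of wandering with
    # the sampling error of a median over a few hundred log-normal draws.
    ranks = np.argsort(np.argsort(shock_c))
    shock_c = sps.norm.ppf((ranks + 0.5) / n) if n > 1 else np.zeros(n)
    target = gp.composite_median_100kcal
    comp = target * np.exp(gp.composite_log_sigma * shock_c)

    # split the composite across the 18 member micronutrients
    k = len(C18_KEYS)
    zero_p = np.array(
        [
            min(0.9, params.zero_content_prob.get(
                key.name, params.zero_content_prob.get("default", 0.0)
            ) * gp.zero_prob_multiplier)
            for key in C18_KEYS
        ]
    )
    zeroed = rng.random((n, k)) < zero_p
    zeroed[zeroed.all(axis=1), _POTASSIUM_IDX] = False  # keep >= 1 member
    gam = rng.gamma(params.dirichlet_concentration, size=(n, k))
    gam[zeroed] = 0.0
    weights = gam / gam.sum(axis=1, keepdims=True)
    contrib = k * comp[:, None] * weights  # %RNI per 100 kcal, mean == comp

    # absolute content per 100 g from the anchoring RNI table
    amounts = {}
    for j, key in enumerate(C18_KEYS):
        amounts[key.name] = contrib[:, j] / 100.0 * rni_table.rni[key] * energy / 100.0
    chloride = sodium * CL_PER_NA * np.exp(0.10 * rng.standard_normal(n))
    rel = comp / target if target > 0 else np.ones(n)  # micronutrient richness

    df = pd.DataFrame(
        {
            "item_id": [f"{group}-{i:04d}" for i in range(n)],
            "name": [f"synthetic {group} item {i:04d}" for i in range(n)],
            "nova": group,
            "is_drink": is_drink,
            "energy_kcal_100g": energy,
            "fat_g_100g": macros["fat"],
            "satfat_g_100g": macros["satfat"],
            "sugar_g_100g": macros["sugar"],
            "sodium_mg_100g": sodium,
        }
    )
    for key in C18_KEYS:
        df[key.column] = amounts[key.name]
    df[registry.SODIUM.column] = sodium
    df[registry.CHLORIDE.column] = chloride

    # micronutrients without an RNI: plausible content scaled by richness
    e100 = energy / 100.0
    for name, base in (
        ("vitamin_e", 0.30), ("pantothenic_acid", 0.50),
        ("biotin", 4.0), ("manganese", 0.25),
    ):
        noise = np.exp(0.5 * rng.standard_normal(n))
        df[registry.key(name).column] = base * rel * noise * e100

    # vitamin A split into retinol + carotenes (A ug RE = retinol + carotene/6)
    vit_a = amounts["vitamin_a"]
    phi = rng.uniform(0.0, 1.0, n)
    retinol = phi * vit_a
    carotene = 6.0 * (1.0 - phi) * vit_a
    df[registry.key("retinol").column] = retinol
    df[registry.key("total_carotene").column] = carotene
    df[registry.key("alpha_carotene").column] = 0.10 * carotene
    df[registry.key("beta_carotene").column] = 0.80 * carotene
    df[registry.key("beta_cryptoxanthin").column] = 0.10 * carotene

    # haem / non-haem iron split (haem only in a minority of items)
    iron = amounts["iron"]
    haem_frac = rng.uniform(0.0, 0.25, n) * (rng.random(n) < 0.3)
    df[registry.key("haem_iron").column] = haem_frac * iron
    df[registry.key("non_haem_iron").column] = (1.0 - haem_frac) * iron

    if gp.zero_energy:
        stem, drink, na = _zero_energy_template(group)
        idx = df.index[-gp.zero_energy:]
        micro_cols = [key.column for key in registry.ALL_KEYS]
        df.loc[idx, ["energy_kcal_100g", "fat_g_100g", "satfat_g_100g", "sugar_g_100g"]] = 0.0
        df.loc[idx, micro_cols] = 0.0
        df.loc[idx, "sodium_mg_100g"] = na
        df.loc[idx, registry.SODIUM.column] = na
        df.loc[idx, registry.CHLORIDE.column] = na * CL_PER_NA
        df.loc[idx, "is_drink"] = drink
        df.loc[idx, "name"] = [f"synthetic zero-energy {stem} {i}" for i in range(gp.zero_energy)]
    return df


def calibration_report(
    items: pd.DataFrame,
    params: GeneratorParams | None = None,
    rni_table: RNITable | None = None,
    thresholds: MTLThresholdSet | None = None,
) -> dict[str, pd.DataFrame]:
    """Realised vs target composite medians and red-light fractions.

    Returns ``{'composite': frame, 'red_lights': frame}`` with relative
    errors against the generator's configured targets.
    """
    params = params if params is not None else load_generator_params()
    rni_table = rni_table if rni_table is not None else load_rni_table(sex="female")
    thresholds = thresholds if thresholds is not None else load_thresholds()

    analysable = items[items["nova"].isin(NOVA_GROUPS) & items["energy_kcal_100g"].notna()]
    contrib = contribution_table(analysable, rni_table, "per100kcal")
    comp_rows = []
    for group in NOVA_GROUPS:
        if group not in params.groups:
            continue
        vals = contrib.loc[analysable["nova"] == group, "composite18"].dropna()
        target = params.groups[group].composite_median_100kcal
        realised = float(vals.median()) if len(vals) else float("nan")
        comp_rows.append(
            {
                "group": group,
                "n": int(len(vals)),
                "target_median": target,
                "realised_median": realised,
                "relative_error": (realised - target) / target if target else float("nan"),
            }
        )
    fopl = classify_table(analysable, thresholds)
    red_rows = []
    for group in NOVA_GROUPS:
        if group not in params.groups:
            continue
        sel = (analysable["nova"] == group).to_numpy()
        for m in MACROS:
            realised = float((fopl.loc[sel, f"fopl_{m}"] == "red").mean())
            target = params.groups[group].red_light_prob[m]
            red_rows.append(
                {
                    "group": group,
                    "nutrient": m,
                    "target_red_fraction": target,
                    "realised_red_fraction": realised,
                    "abs_error": realised - target,
                }
            )
    return {"composite": pd.DataFrame(comp_rows), "red_lights": pd.DataFrame(red_rows)}


def simulate_logistic_outcomes(
    n: int,
    log_odds: Mapping[str, float],
    intercept: float = 0.0,
    nova_probs: Mapping[str, float] | None = None,
    p_healthy: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (nova, healthy, outcome) with known true log-odds.

    ``log_odds`` maps covariate names ('nova_UPF', 'nova_PF', 'nova_PCI',
    'unhealthy') to true coefficients relative to the MPF/healthy
    reference. Used for parameter-recovery and CI-coverage checks of the
    logistic model.
    """
    rng = np.random.default_rng(seed)
    if nova_probs is None:
        nova_probs = {"MPF": 986 / 2980, "PCI": 61 / 2980, "PF": 283 / 2980, "UPF": 1650 / 2980}
    groups = list(nova_probs)
    nova = rng.choice(groups, size=n, p=[nova_probs[g] for g in groups])
    healthy = rng.random(n) < p_healthy
    eta = np.full(n, intercept, dtype=float)
    for g in groups:
        if f"nova_{g}" in log_odds:
            eta += log_odds[f"nova_{g}"] * (nova == g)
    eta += log_odds.get("unhealthy", 0.0) * (~healthy)
    p = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"outcome": outcome, "nova": nova, "healthy": healthy})
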