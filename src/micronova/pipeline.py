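"""End-to-end orchestration: ingest -> FOPL -> scoring -> statistics -> report.

The pipeline keeps an explicit exclusion ledger (no silent row loss): total
rows, minus items coded outside the four Nova groups, minus items with no
matching nutrient data, give the analysable set; the per-100 kcal basis
additionally drops zero-energy items; composite scores are additionally
missing for items lacking any composite-member micronutrient (the two
selenium-missing UPF in the reference databank).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, registry
from .core import (
    NOVA_GROUPS,
    MTLThresholdSet,
    RNITable,
    load_rni_table,
    load_thresholds,
    read_item_table,
    validate_items,
)
from .fopl import classify_table
from .scoring import BASES, contribution_table, diet_attainment, zero_content_proportions
from .stats import (
    SeparationError,
    crosstab_chi2,
    fit_logistic,
    kruskal_wallis,
    letter_display,
    mann_whitney,
    median_split,
    pairwise_bonferroni,
    quartile_assign,
    summarise_groups,
)

#: Recommended daily energy intake used for diet-attainment scaling.
KCAL_TARGET = {"female": 2000.0, "male": 2500.0}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on."""

    item_table: str | Path | None = None  # path; None -> generate synthetically
    generator_params: str | Path | None = None  # optional params file for generation
    rni_config: str | Path | None = None
    threshold_config: str | Path | None = None
    sex: str = "female"
    bases: tuple[str, ...] = ("per100g", "per100kcal")
    seed: int = 1
    sensitivity_composite20: bool = True

    def __post_init__(self) -> None:
        if self.sex not in KCAL_TARGET:
            raise ValueError(f"sex must be one of {sorted(KCAL_TARGET)}")
        bad = set(self.bases) - set(BASES)
        if bad:
            raise ValueError(f"unknown bases: {sorted(bad)}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "item_table": str(self.item_table),
                "generator_params": str(self.generator_params),
                "rni_config": str(self.rni_config),
                "threshold_config": str(self.threshold_config),
                "sex": self.sex,
                "bases": list(self.bases),
                "seed": self.seed,
                "sensitivity_composite20": self.sensitivity_composite20,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """All pipeline outputs for one sex, keyed the way the tables are written."""

    config: RunConfig
    ledger: dict[str, int]
    validation_issues: list[str]
    group_summaries: dict[str, pd.DataFrame]  # per basis
    pairwise: dict[str, pd.DataFrame]
    letters: dict[str, dict[str, str]]
    strata_summaries: dict[str, pd.DataFrame]  # healthy/unhealthy x group
    healthy_vs_unhealthy: dict[str, pd.DataFrame]  # Mann-Whitney battery
    quartile_tables: dict[str, pd.DataFrame]
    quartile_tests: dict[str, pd.DataFrame]
    logistic: dict[str, pd.DataFrame]
    diet_attainment: pd.DataFrame
    zero_content: pd.DataFrame
    sensitivity: dict[str, pd.DataFrame] = field(default_factory=dict)


def _summaries_frame(scores, labels) -> pd.DataFrame:
    rows = [
        {"group": s.group, "n": s.n, "median": s.median, "q25": s.q25, "q75": s.q75}
        for s in summarise_groups(scores, labels)
    ]
    return pd.DataFrame(rows)


def _pairwise_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.comparison[0],
                "group_b": r.comparison[1],
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "p_bonferroni": r.p_adjusted,
                "method": r.method,
            }
            for r in results
        ]
    )


def load_analysable(config: RunConfig) -> tuple[pd.DataFrame, dict[str, int], list[str]]:
    """Ingest the item table and apply the pre-analysis exclusion ledger."""
    if config.item_table is not None:
        items = read_item_table(config.item_table)
    else:
        from .synth import generate_items, load_generator_params

        params = load_generator_params(config.generator_params)
        items = generate_items(params, seed=config.seed)
    issues = [str(i) for i in validate_items(items)]

    n_total = len(items)
    non_nova = ~items["nova"].isin(NOVA_GROUPS)
    items = items[~non_nova]
    unmatched = items["energy_kcal_100g"].isna()
    items = items[~unmatched].reset_index(drop=True)
    ledger = {
        "total_items": n_total,
        "excluded_non_nova": int(non_nova.sum()),
        "excluded_unmatched": int(unmatched.sum()),
        "analysable": len(items),
    }
    assert ledger["analysable"] == n_total - ledger["excluded_non_nova"] - ledger["excluded_unmatched"]
    return items, ledger, issues


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute the full comparison battery for one sex."""
    rni = load_rni_table(config.rni_config, sex=config.sex)
    thresholds = load_thresholds(config.threshold_config)
    items, ledger, issues = load_analysable(config)

    fopl = classify_table(items, thresholds)
    healthy = fopl["healthy"].to_numpy()
    nova = items["nova"].to_numpy()

    group_summaries: dict[str, pd.DataFrame] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    strata_summaries: dict[str, pd.DataFrame] = {}
    hvu: dict[str, pd.DataFrame] = {}
    quartile_tables: dict[str, pd.DataFrame] = {}
    quartile_tests: dict[str, pd.DataFrame] = {}
    logistic: dict[str, pd.DataFrame] = {}
    sensitivity: dict[str, pd.DataFrame] = {}
    attain_rows = []

    for basis in config.bases:
        contrib = contribution_table(items, rni, basis)
        if basis == "per100kcal":
            included = ~contrib["excluded_zero_energy"].to_numpy()
            ledger["excluded_zero_energy"] = int((~included).sum())
            ledger["per100kcal_items"] = int(included.sum())
        else:
            included = np.ones(len(items), dtype=bool)
        comp = contrib["composite18"].to_numpy()
        comp_n = int(np.sum(included & ~np.isnan(comp)))
        ledger[f"composite18_complete_{basis}"] = comp_n

        sel = included & ~np.isnan(comp)
        scores, glab, hlab = comp[sel], nova[sel], healthy[sel]

        group_summaries[basis] = _summaries_frame(scores, glab)
        pw = pairwise_bonferroni(scores, glab, method="asymptotic")
        pairwise[basis] = _pairwise_frame(pw)
        letters[basis] = letter_display(list(pd.unique(glab)), pw)

        # healthy / unhealthy strata: summaries within each stratum x group
        strata = []
        for flag, name in ((True, "healthy"), (False, "unhealthy")):
            sub = hlab == flag
            frame = _summaries_frame(scores[sub], glab[sub])
            frame.insert(0, "stratum", name)
            strata.append(frame)
            overall = _summaries_frame(scores[sub], np.repeat("all", sub.sum()))
            overall.insert(0, "stratum", name)
            strata.append(overall)
        strata_summaries[basis] = pd.concat(strata, ignore_index=True)

        # Mann-Whitney healthy vs unhealthy: overall and within each group
        rows = []
        for scope in ("all",) + tuple(NOVA_GROUPS):
            m = np.ones(len(scores), bool) if scope == "all" else glab == scope
            a, b = scores[m & hlab], scores[m & ~hlab]
            if len(a) == 0 or len(b) == 0:
                continue
            r = mann_whitney(a, b, method="asymptotic", comparison=("healthy", "unhealthy"))
            rows.append(
                {"scope": scope, "n_healthy": len(a), "n_unhealthy": len(b),
                 "U": r.statistic, "p": r.p}
            )
        hvu[basis] = pd.DataFrame(rows)

        # quartiles of the composite: cross-tab against Nova and FOPL status
        quart = quartile_assign(scores)
        t_nova, r_nova = crosstab_chi2(quart, glab)
        t_fopl, r_fopl = crosstab_chi2(quart, np.where(hlab, "healthy", "unhealthy"))
        t_nova.index.name = t_fopl.index.name = "quartile"
        quartile_tables[f"{basis}_nova"] = t_nova
        quartile_tables[f"{basis}_fopl"] = t_fopl
        quartile_tests[basis] = pd.DataFrame(
            [
                {"table": "nova", "chi2": r_nova.statistic, "df": r_nova.df, "p": r_nova.p},
                {"table": "fopl", "chi2": r_fopl.statistic, "df": r_fopl.df, "p": r_fopl.p},
            ]
        )

        # above-median contribution ~ Nova + FOPL
        outcome = median_split(scores)
        try:
            fit = fit_logistic(outcome, glab, hlab)
            terms = fit.terms.copy()
            terms["n"] = fit.n
            logistic[basis] = terms
        except SeparationError as e:  # pragma: no cover - depends on data
            logistic[basis] = pd.DataFrame({"error": [str(e)]})

        if config.sensitivity_composite20:
            comp20 = contrib["composite20"].to_numpy()
            sel20 = included & ~np.isnan(comp20)
            sensitivity[basis] = _summaries_frame(comp20[sel20], nova[sel20])

        if basis == "per100kcal":
            # per-group micronutrient medians scaled to the daily kcal target
            for group in ("all",) + tuple(NOVA_GROUPS):
                m = included if group == "all" else (included & (nova == group))
                med = {
                    k: float(np.nanmedian(contrib.loc[m, f"pct_{k.name}"]))
                    for k in registry.RNI_KEYS
                }
                res = diet_attainment(med, KCAL_TARGET[config.sex])
                res80_only = res.attained_80 - res.attained
                attain_rows.append(
                    {
                        "group": group,
                        "kcal_target": KCAL_TARGET[config.sex],
                        "n_met": res.count,
                        "n_met_80": res.count_80,
                        "met": ",".join(sorted(k.name for k in res.attained)),
                        "met_80_only": ",".join(sorted(k.name for k in res80_only)),
                    }
                )

    zero = pd.concat(
        [zero_content_proportions(items, k) for k in registry.RNI_KEYS], axis=1
    ).T
    zero.index.name = "micronutrient"

    if "per100kcal" in config.bases:
        h_n = int(np.sum(healthy))
        ledger["healthy_items"] = h_n
        ledger["unhealthy_items"] = int(len(items) - h_n)

    return ComparisonReport(
        config=config,
        ledger=ledger,
        validation_issues=issues,
        group_summaries=group_summaries,
        pairwise=pairwise,
        letters=letters,
        strata_summaries=strata_summaries,
        healthy_vs_unhealthy=hvu,
        quartile_tables=quartile_tables,
        quartile_tests=quartile_tests,
        logistic=logistic,
        diet_attainment=pd.DataFrame(attain_rows),
        zero_content=zero,
        sensitivity=sensitivity,
    )


def write_report(report: ComparisonReport, out_dir: str | Path) -> list[Path]:
    """Write per-table delimited files plus a machine-readable run manifest.

    File names are stable; numeric content is full precision (reporting
    layers round for display). Two runs with identical config and seed
    produce byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e

    written: list[Path] = []

    def save(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=index)
        written.append(path)

    for basis, frame in report.group_summaries.items():
        save(frame, f"summary_{basis}")
    for basis, frame in report.pairwise.items():
        save(frame, f"pairwise_{basis}")
    for basis, frame in report.strata_summaries.items():
        save(frame, f"strata_{basis}")
    for basis, frame in report.healthy_vs_unhealthy.items():
        save(frame, f"healthy_vs_unhealthy_{basis}")
    for name, frame in report.quartile_tables.items():
        save(frame, f"quartiles_{name}", index=True)
    for basis, frame in report.quartile_tests.items():
        save(frame, f"quartile_tests_{basis}")
    for basis, frame in report.logistic.items():
        save(frame, f"logistic_{basis}", index=True)
    for basis, frame in report.sensitivity.items():
        save(frame, f"sensitivity_composite20_{basis}")
    save(report.diet_attainment, "diet_attainment")
    save(report.zero_content, "zero_content", index=True)

    manifest = {
        "package_version": __version__,
        "config_hash": report.config.config_hash(),
        "seed": report.config.seed,
        "sex": report.config.sex,
        "bases": list(report.config.bases),
        "ledger": report.ledger,
        "letters": report.letters,
        "n_validation_issues": len(report.validation_issues),
        "files": sorted(p.name for p in written) + ["manifest.json"],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
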