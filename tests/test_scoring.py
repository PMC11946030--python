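import math

import numpy as np
import pandas as pd
import pytest

from micronova import registry
from micronova.core import FoodItem
from micronova.scoring import (
    ZeroEnergyExclusion,
    composite,
    contribution,
    contribution_table,
    count_recommendations_met,
    diet_attainment,
    per_100kcal_density,
    zero_content_proportions,
)
from micronova.synth import generate_items

VITC = registry.key("vitamin_c")
IRON = registry.key("iron")
SE = registry.key("selenium")


def make_item(energy=100.0, micro=None, **kw):
    defaults = dict(
        item_id="x", name="x", nova="MPF", is_drink=False,
        energy_kcal_100g=energy, fat_g_100g=0.0, satfat_g_100g=0.0,
        sugar_g_100g=0.0, sodium_mg_100g=0.0,
    )
    defaults.update(kw)
    return FoodItem(micronutrients=micro or {}, **defaults)


class TestPer100kcalDensity:
    def test_formula(self):
        item = make_item(energy=50.0, micro={VITC: 20.0})
        assert per_100kcal_density(item)[VITC] == pytest.approx(40.0)

    def test_identity_at_100_kcal(self):
        item = make_item(energy=100.0, micro={VITC: 7.0})
        assert per_100kcal_density(item)[VITC] == pytest.approx(7.0)

    def test_zero_energy_item_excluded(self):
        assert per_100kcal_density(make_item(energy=0.0, micro={VITC: 1.0})) is None


class TestContribution:
    def test_iron_at_the_female_rni_contributes_100_percent(self, rni_female):
        item = make_item(micro={IRON: 14.8})
        prof = contribution(item, rni_female, "per100g")
        assert prof.contrib[IRON] == pytest.approx(100.0)

    def test_all_zero_content_gives_zero_contributions(self, rni_female):
        item = make_item(micro={k: 0.0 for k in rni_female.rni})
        prof = contribution(item, rni_female, "per100g")
        assert all(v == 0.0 for v in prof.contrib.values())
        assert prof.composite18 == 0.0

    def test_per100kcal_rescales_by_energy(self, rni_female):
        # 7.4 mg Fe/100 g at 200 kcal/100 g -> 3.7 mg per 100 kcal -> 25% of 14.8
        item = make_item(energy=200.0, micro={IRON: 7.4})
        prof = contribution(item, rni_female, "per100kcal")
        assert prof.contrib[IRON] == pytest.approx(25.0)

    def test_zero_energy_item_raises_explicit_exclusion(self, rni_female):
        with pytest.raises(ZeroEnergyExclusion):
            contribution(make_item(energy=0.0), rni_female, "per100kcal")


class TestComposite:
    def test_mean_of_constant_contributions(self, rni_female):
        contrib = {k: 10.0 for k in rni_female.composite18}
        assert composite(contrib, rni_female.composite18) == pytest.approx(10.0)

    def test_unbounded_contributions_average_through(self, rni_female):
        keys = sorted(rni_female.composite18, key=lambda k: k.name)
        contrib = {k: 0.0 for k in keys}
        contrib[keys[0]] = 180.0
        assert composite(contrib, rni_female.composite18) == pytest.approx(10.0)

    def test_missing_member_makes_composite_missing(self, rni_female):
        micro = {k: 1.0 for k in rni_female.rni if k != SE}
        prof = contribution(make_item(micro=micro), rni_female, "per100g")
        assert prof.composite18 is None
        assert prof.composite20 is None
        assert IRON in prof.contrib  # other contributions survive

    def test_empty_key_set_rejected(self):
        with pytest.raises(ValueError):
            composite({}, frozenset())

    def test_composite18_blind_to_sodium_chloride_vitamin_e(self, rni_female, databank):
        perturbed = databank.copy()
        for name in ("sodium", "chloride", "vitamin_e"):
            perturbed[registry.key(name).column] = (
                perturbed[registry.key(name).column] * 7 + 3
            )
        a = contribution_table(databank, rni_female, "per100g")["composite18"]
        b = contribution_table(perturbed, rni_female, "per100g")["composite18"]
        pd.testing.assert_series_equal(a, b)


class TestTableInvariants:
    def test_scaling_identity_between_bases(self, rni_female, databank):
        g = contribution_table(databank, rni_female, "per100g")
        k = contribution_table(databank, rni_female, "per100kcal")
        energy = databank["energy_kcal_100g"].to_numpy()
        ok = (energy > 0) & g["composite18"].notna()
        expected = g.loc[ok, "composite18"] * 100.0 / energy[ok]
        rel = np.abs(k.loc[ok, "composite18"] - expected) / expected
        assert float(rel.max()) < 1e-10

    def test_contributions_homogeneous_in_content(self, rni_female, databank):
        doubled = databank.copy()
        for k in registry.ALL_KEYS:
            doubled[k.column] = doubled[k.column] * 2
        a = contribution_table(databank, rni_female, "per100g")
        b = contribution_table(doubled, rni_female, "per100g")
        pd.testing.assert_frame_equal(
            b.drop(columns="excluded_zero_energy"),
            a.drop(columns="excluded_zero_energy") * 2,
        )

    def test_zero_energy_rows_flagged_not_zeroed(self, rni_female, databank):
        k = contribution_table(databank, rni_female, "per100kcal")
        zero = databank["energy_kcal_100g"] == 0
        assert (k.loc[zero, "excluded_zero_energy"]).all()
        assert k.loc[zero, "composite18"].isna().all()


class TestZeroContentProportions:
    def _table(self):
        df = generate_items(seed=3).head(8).copy()
        df["nova"] = ["MPF"] * 4 + ["UPF"] * 4
        return df

    def test_all_zero_gives_one(self):
        df = self._table()
        df[VITC.column] = 0.0
        props = zero_content_proportions(df, VITC)
        assert props["overall"] == 1.0

    def test_half_zero_gives_half(self):
        df = self._table()
        df[VITC.column] = [0.0, 1.0] * 4
        assert zero_content_proportions(df, VITC)["overall"] == 0.5

    def test_group_specific_zeros(self):
        df = self._table()
        df[VITC.column] = [1.0] * 4 + [0.0, 1.0, 1.0, 1.0]
        props = zero_content_proportions(df, VITC)
        assert props["MPF"] == 0.0
        assert props["UPF"] == pytest.approx(0.25)

    def test_missing_values_not_counted_as_zero(self):
        df = self._table()
        df[VITC.column] = [0.0, np.nan, 1.0, 1.0] + [1.0] * 4
        # 7 non-missing, 1 zero
        assert zero_content_proportions(df, VITC)["overall"] == pytest.approx(1 / 7)


class TestDietAttainment:
    def test_exact_boundary_attains(self):
        res = diet_attainment({IRON: 5.0}, 2000.0)
        assert res.attained == {IRON}

    def test_just_below_meets_only_the_80_percent_bar(self):
        res = diet_attainment({IRON: 4.9}, 2000.0)
        assert res.count == 0
        assert res.attained_80 == {IRON}

    def test_zero_contributions_attain_nothing(self):
        res = diet_attainment({IRON: 0.0, VITC: 0.0}, 2000.0)
        assert res.count == 0 and res.count_80 == 0

    def test_monotone_in_energy_target(self):
        med = {IRON: 4.0, VITC: 6.0, SE: 1.0}
        counts = [diet_attainment(med, t).count for t in np.linspace(500, 6000, 23)]
        assert counts == sorted(counts)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            diet_attainment({IRON: 5.0}, 0.0)


class TestCountRecommendationsMet:
    def test_intake_at_rni_meets_all_18(self, rni_female):
        intake = {k: v for k, v in rni_female.rni.items()}
        assert count_recommendations_met(intake, rni_female) == 18

    def test_zero_intake_meets_none(self, rni_female):
        intake = {k: 0.0 for k in rni_female.rni}
        assert count_recommendations_met(intake, rni_female) == 0

    def test_partial_intake_counts_exactly_the_met_keys(self, rni_female):
        vitamins = [k for k in rni_female.composite18 if k.name.startswith(("vitamin", "thiamin"))]
        chosen = sorted(vitamins, key=lambda k: k.name)[:6] + sorted(
            (k for k in rni_female.composite18 if k.name in ("iron", "zinc", "calcium", "iodine")),
            key=lambda k: k.name,
        )
        intake = {k: 0.0 for k in rni_female.rni}
        for k in chosen:
            intake[k] = rni_female.rni[k]
        assert count_recommendations_met(intake, rni_female) == len(chosen) == 10

    def test_missing_intake_warns_and_counts_as_not_met(self, rni_female):
        intake = {k: v for k, v in rni_female.rni.items() if k.name != "iodine"}
        with pytest.warns(UserWarning, match="iodine"):
            assert count_recommendations_met(intake, rni_female) == 17
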