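# micronova

Micronutrient profiling of food and drink databanks across **Nova**
food-processing groups and UK **multiple-traffic-light (MTL)**
front-of-package labels.

## The problem

UK dietary guidance is communicated in retail through MTL front-of-package
labels (green/amber/red for fat, saturated fat, total sugar and salt per
100 g), while a growing literature classifies items by degree of
processing (Nova: minimally processed food MPF, processed culinary
ingredients PCI, processed food PF, ultra-processed food UPF). These two
lenses only partially overlap, and neither says directly how well an item
helps meet government **reference nutrient intakes (RNIs)** for vitamins
and minerals. This package implements an item-level analysis that connects
the three: for every item in an NDNS-style nutrient databank it computes
the percent contribution to each RNI, aggregates these into a composite
micronutrient score, and asks whether that score differs by Nova group
once the MTL healthy/unhealthy dichotomy is accounted for.

It is written for nutrition and public-health researchers who have (or can
request) a nutrient databank with one row per item: energy and
macronutrients per 100 g, ~30 micronutrients per 100 g, an externally
assigned Nova label, and a drink flag. Because the UK NDNS nutrient
databank is a restricted download, the package ships a calibrated
synthetic databank generator with the same statistical structure, so the
whole pipeline is runnable and testable out of the box.

## The model

For item *i* with micronutrient content $x_{ik}$ (per 100 g, canonical
units) and energy density $E_i$ (kcal/100 g):

* per-100 kcal content: $x^{kcal}_{ik} = x_{ik} \cdot 100 / E_i$ (items
  with $E_i = 0$ — water, weak tea, salt, no-calorie sweeteners — are
  excluded from this basis);
* percent RNI contribution on basis $b$: $c^b_{ik} = 100 \cdot x^b_{ik} /
  \mathrm{RNI}_k$, uncapped;
* composite score: the unweighted mean of $c^b_{ik}$ over 18
  micronutrients (all RNI-bearing ones except sodium and chloride, which
  are nutrients to limit; vitamin E has no UK government RNI). A
  sensitivity variant (/20) adds sodium and chloride back. An item missing
  any member has a missing composite but keeps its per-nutrient values.

MTL colours follow the FSA cut-offs per 100 g (drinks use the lower drink
cut-offs, 100 ml ≡ 100 g; a value exactly at a cut keeps the lower
colour); an item is *healthy* iff it has no red light. Groups are compared
with medians/IQRs, Kruskal–Wallis ANOVA with Bonferroni-corrected pairwise
comparisons, Mann–Whitney U for healthy vs unhealthy, χ² tests on
quartile cross-tabs, and a binary logistic model of the odds of an
above-median composite on Nova group + MTL status (reference MPF,
healthy). A diet-attainment counter scales each group's median per-100 kcal
contributions to a daily energy target (2000 kcal female / 2500 kcal male)
and counts the RNIs met at 100 % and 80 %.

## Worked example

Run the numbered analysis scripts in order (or equivalently the
`micronova run-all` CLI):

```sh
python analysis/01_generate_databank.py   # synthetic databank, 2980 items
python analysis/02_classify_fopl.py       # traffic lights + healthy flag
python analysis/03_score_contributions.py # %RNI on both bases
python analysis/04_compare_groups.py      # statistical battery
python analysis/05_attainment_and_sensitivity.py
```

`04_compare_groups.py` prints (synthetic databank, seed 1, female RNIs):

```
composite (/18) per 100 kcal by Nova group (median [IQR]):
  MPF    14.3 [7.8, 26.3]  a
  PCI     0.9 [0.2, 3.6]  b
  PF      7.7 [5.0, 11.8]  c
  UPF     5.8 [3.3, 10.3]  d

odds of above-median contribution per 100 kcal (reference MPF, healthy):
  nova_UPF  OR 0.23 (95% CI 0.20-0.28)  | inverse 4.3
  nova_PF   OR 0.36 (95% CI 0.27-0.48)  | inverse 2.8
  nova_PCI  OR 0.09 (95% CI 0.04-0.18)  | inverse 11.7
  unhealthy OR 0.48 (95% CI 0.41-0.56)  | inverse 2.1
```

Reading this: per 100 kcal the median MPF item contributes 14.3 % of a
female RNI per micronutrient, PF 7.7 % and UPF 5.8 %; all pairwise
distributions differ (unlike letters, Bonferroni-adjusted p < 0.05). After
adjusting for the MTL healthy/unhealthy status, an MPF item has 4.3 times
the odds of an above-median micronutrient contribution per 100 kcal
compared with a UPF item (the `nova_UPF` row shows the same effect in the
UPF-vs-MPF direction, OR 0.23). Tables land in `results/comparison/`,
together with a machine-readable `manifest.json` recording the exclusion
ledger (2980 analysable → 2955 per-100 kcal after removing 25 zero-energy
items → 2953 with complete selenium).

To run on a real databank, export it to CSV with the canonical column
names (see `micronova/registry.py`), then:

```sh
micronova compare your_databank.csv --out results/real --sex female
```

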