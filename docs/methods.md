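# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Scope and data model

One row per food or drink item: identity, an externally assigned Nova
label (MPF / PCI / PF / UPF — Nova coding is a manual, judgement-based
process and is deliberately an *input*, never inferred), a drink flag,
energy (kcal/100 g), the four front-of-package macronutrients (fat,
saturated fat, total sugar in g/100 g; sodium in mg/100 g) and ~30
micronutrients per 100 g. A single registry
(`micronova/registry.py`) fixes each micronutrient's canonical unit; all
I/O converts at the boundary, so a quantity can never silently change
units between stages. Twenty micronutrients carry a UK RNI; vitamin E,
pantothenic acid, biotin, manganese, retinol, the carotene fractions and
the haem/non-haem iron split are carried as absolute content only and
never enter percent-contribution arithmetic.

Missing is distinct from zero throughout: an empty cell in a delimited
table is NaN, zero content is an analysable fact (reported as zero-content
proportions), and a missing composite-member micronutrient makes the
composite missing while leaving the per-nutrient contributions intact.
CSV reads use round-trip float parsing so that write → read → write
reproduces the identical decimal text.

## Reference nutrient intakes

RNIs ship as editable YAML, one file per sex (19–64 y), sourced from the
UK COMA (1991) dietary reference values as carried in current government
guidance, with vitamin D from SACN (2016). Iron for females uses the
19–49 y value (14.8 mg/d). These are configuration, not constants: any
value can be overridden by pointing the loaders at another file, and the
loader rejects files that omit a composite member, use a non-canonical
unit, or contain non-positive values. Sex is purely a configuration axis
(RNI table plus the 2000 vs 2500 kcal/day attainment target); no code path
branches on it.

## Traffic-light classification

Cut-offs default to the FSA front-of-pack guidance (g per 100 g; drinks
use the lower drink cut-offs with 100 ml treated as 100 g). Salt is
derived from sodium (salt g = Na mg × 2.5/1000) unless an explicit salt
column is supplied, which then wins. Two conventions are fixed and
config-independent:

* **Boundary rule.** A value exactly at a cut-off keeps the lower colour
  (≤ amber-cut → green; ≤ red-cut → amber; above → red). The guidance
  wording ("low/medium/high") does not settle this; one documented
  convention beats an implicit one.
* **Strictly per 100 g.** The per-portion red override for large portions
  in the full FSA scheme is intentionally not implemented; classification
  is comparable across items only on a common 100 g basis.

An item is *healthy* iff it has no red light — the dichotomy consumers
act on most strongly — and no further aggregate FOPL score is computed.

## Contributions and composites

Per-100 kcal content divides per-100 g content by energy density and
multiplies by 100; items with energy exactly 0 (the equality is exact, not
a small-ε band: such items are waters, weak teas, salts and no-calorie
sweeteners whose stored energy is a literal 0) are excluded from the
per-100 kcal basis with an explicit flag, never silently zeroed.
Contributions are uncapped — per-100 kcal medians above 100 % are
meaningful and occur for culinary ingredients. The composite is an
unweighted arithmetic mean over its membership set; no energy or nutrient
weighting. The /18 headline set excludes sodium and chloride (nutrients to
limit) and vitamin E (no UK government RNI; its contribution is computable
on request if an RNI is supplied, but the shipped configs leave it unset);
the /20 sensitivity set adds sodium and chloride back.

Diet attainment scales a vector of median per-100 kcal contributions by
kcal-target/100 and counts micronutrients reaching 100 % (and 80 %) of
the RNI; it is monotone in the energy target by construction. The intake
counter for daily-diet vectors compares intake with the RNI over the /18
set, warning on (and not counting) missing entries.

## Statistical battery

Description uses medians and IQRs; all quantile computations (median, IQR,
quartile cuts) use linear interpolation between order statistics — one
documented convention everywhere. Quartile assignment puts a value exactly
at a cut into the lower quartile, so counts always partition the sample.
The median split for the logistic outcome is strict (> median is 1; at or
below is 0), which is asymmetric under sign flips and is documented as
such.

Pairwise group comparisons are two-group Kruskal–Wallis tests (not Dunn's
test on pooled ranks), Bonferroni-multiplied by the number of pairs
actually tested and capped at 1; a compact letter display marks groups
whose adjusted p ≥ 0.05 as sharing a letter. The Mann–Whitney U test uses
midranks with tie correction and continuity correction in its normal
approximation; a two-group Kruskal–Wallis equals it up to that continuity
correction, which the tests assert.

**Small samples.** The χ² approximation to Kruskal–Wallis and the normal
approximation to Mann–Whitney are unreliable below about a dozen
observations: enumeration shows deviations from the exact permutation
p-value exceeding 0.1 at n ≤ 8. Both tests therefore enumerate the
permutation null exhaustively whenever the number of distinct label
assignments is ≤ 20 000 (every n ≤ 8 case, and most n ≤ 10 two-group
cases), returning the exact p (for Mann–Whitney, the symmetric two-sided
tail P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|); for Kruskal–Wallis,
P(H ≥ H_obs)). Study-scale comparisons (groups of tens to thousands)
always take the asymptotic path. Constant data short-circuit to H = 0,
p = 1 (the tie-correction denominator would otherwise vanish).

χ² tests on r×c tables use Pearson's statistic with (r−1)(c−1) df and no
continuity correction; the Yates correction for 2×2 tables is available
but off by default. Degenerate single-category margins are an error, not
a silent p = 1.

The logistic model is fit by IRLS (maximum likelihood) with Wald 95 % CIs,
reference levels MPF and healthy; odds ratios are reported in both
directions (level-vs-reference and its reciprocal with swapped CI bounds).
Complete or quasi-complete separation is detected (a dummy level whose
outcomes are constant, or a diverging coefficient) and raised as an error
naming the covariate; PCI, with only 61 items in the reference databank,
is the realistic candidate and is reported with its (wide) CI when
estimable. Covariates without variation are dropped rather than handed to
the optimiser as a singular design.

## Synthetic databank generator

The generator emulates the joint structure the analysis is sensitive to,
at the reference scale of 2980 items (986 MPF, 61 PCI, 283 PF, 1650 UPF),
with 25 zero-energy items and 2 selenium-missing UPF rows injected.

* **Composite density.** Each item's composite %RNI per 100 kcal is drawn
  log-normally with median equal to its group's target (defaults 14.4 /
  0.9 / 7.7 / 5.8 for MPF / PCI / PF / UPF) and log-scale σ set from the
  corresponding IQRs (0.91 / 2.2 / 0.64 / 0.85). The draw is
  *stratified*: iid latent shocks are rank-mapped onto exact normal
  quantiles, so the realised group median sits at the target for every
  seed instead of wandering with the ~5 % sampling error a median over a
  few hundred log-normal draws would otherwise have. Spread, skew and
  latent correlations are unaffected.
* **Per-nutrient split.** The composite is split across the 18 member
  micronutrients by a symmetric Dirichlet weight vector (concentration 4),
  which makes the item's mean contribution equal its composite *exactly* —
  the calibration is algebraic, not fitted. Per-key zero-content
  inflation (e.g. vitamin D absent in ~45 % of items, scaled per group)
  zeroes members before re-normalising the weights, so composites are
  unchanged while zero-content proportions are realistic.
* **Macronutrients and energy.** Fat, saturated fat, sugar and salt are
  log-normal with location calibrated so that P(value > red cut) equals
  the configured per-group red-light probability exactly (per dialect —
  drinks are calibrated against drink cuts); total fat is floored at
  saturated fat. Energy is 9·fat + 4·sugar + a log-normal remainder
  (proteins and non-sugar carbohydrate), so energy-dense items are
  mechanically the fatty/sugary ones.
* **Latent unhealthiness.** A single standard-normal factor per item
  enters the macronutrient shocks (ρ = 0.55), the energy remainder
  (ρ = 0.55) and, negatively, the composite density (ρ = −0.40). This one
  knob reproduces the qualitative pattern of retail food data: unhealthy
  items are denser per 100 g but poorer per 100 kcal, and the Nova
  gradient survives adjustment for the healthy/unhealthy flag.
* **Fixed structure.** Sodium/chloride contributions derive from the salt
  draw (chloride at the NaCl mass ratio with 10 % log-noise), not from the
  Dirichlet split; vitamin A is split into retinol and carotene fractions
  consistent with retinol equivalents; haem iron occurs in ~30 % of items
  at up to 25 % of total iron. Non-RNI micronutrients scale with the
  item's overall micronutrient richness.

Group sizes, composite targets and σ, the zero-energy and selenium-missing
counts are the reference study conditions. Red-light probabilities, drink
fractions, energy remainders and zero-content rates are not reported at
that granularity anywhere; the shipped defaults were chosen once as
realistic for a UK retail supply (e.g. UPF red-light rates of 18–28 %
against 2–10 % for MPF; energy remainder medians of 55–300 kcal/100 g)
and are ordinary configuration in `data/generator_defaults.yaml`.

What the generator does **not** emulate: real food names and subgroup
taxonomies, fortification policy, the true joint covariance between
specific micronutrients (a single richness factor stands in for it), or
realistic per-key medians — so diet-attainment counts on synthetic data
are internally consistent but not comparable to counts from the real
databank. Passing tests therefore demonstrate correctness of the
*machinery* and recovery of direction-level structure, not agreement with
real-data magnitudes, which require the UK Data Service databank as input.

## Problem sizes and numerics

The default test suite and the acceptance script run at the reference
scale (2980 items), with a 10 000-item table for the basis-scaling and
traffic-light property checks, exhaustive permutation enumeration at n ≤ 8
per test case, and 100 replicate logistic fits at n = 2000 for CI
coverage; the whole suite completes in well under a minute on one CPU.
Floating-point tolerances: the per-100 kcal / per-100 g composite identity
(ratio 100/E) holds to ~1e-15 relative and is asserted at 1e-10;
statistical agreement assertions use absolute tolerances stated in each
test. Exclusion ledgers are asserted to be exactly conservative at every
stage (no silent row loss). Reported tables round to one decimal at the
display layer only; written CSVs keep full precision, and the run manifest
records config hash, seed, package version and every exclusion count, so a
run can be reproduced byte-identically from its manifest inputs.

## Known limitations

* No portion-size modelling: everything is per 100 g or per 100 kcal.
* Nova labels are taken as given; coding disagreement between human raters
  is outside the model.
* Whether databank "total sugar" coincides with label "sugars" is treated
  as exact identity.
* The logistic model is cross-sectional with two categorical covariates;
  no survey weights, clustering or interaction terms.
* Synthetic per-nutrient marginal distributions are exchangeable within
  the Dirichlet split; real nutrient co-occurrence (e.g. B12 with haem
  iron) is only weakly represented through the shared richness factor.
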