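# Default parameters for the synthetic NDNS-like nutrient databank.
#
# Group sizes and the per-100 kcal composite-median targets reproduce the
# study conditions of the UK Year-12 NDNS databank analysis this package
# implements (2980 analysable items: 986 MPF, 61 PCI, 283 PF, 1650 UPF;
# composite %RNI-per-100-kcal medians 14.4 / 0.9 / 7.7 / 5.8; 25
# zero-energy items; 2 UPF rows with missing selenium). Spread parameters
# are set on the log scale from the reported interquartile ranges.
# Red-light probabilities, drink fractions, energy remainders and
# zero-content rates are not reported at this granularity and are chosen
# once as realistic for a UK retail food supply; see docs/methods.md.
groups:
  MPF:
    n: 986
    composite_median_100kcal: 14.4
    composite_log_sigma: 0.91
    drink_fraction: 0.10
    red_light_prob: {fat: 0.10, satfat: 0.08, sugar: 0.10, salt: 0.02}
    energy_remainder_median: {food: 55.0, drink: 25.0}
    zero_prob_multiplier: 0.8
    zero_energy: 15
  PCI:
    n: 61
    composite_median_100kcal: 0.9
    composite_log_sigma: 2.2
    drink_fraction: 0.0
    red_light_prob: {fat: 0.45, satfat: 0.35, sugar: 0.08, salt: 0.25}
    energy_remainder_median: {food: 300.0, drink: 100.0}
    zero_prob_multiplier: 1.5
    zero_energy: 5
  PF:
    n: 283
    composite_median_100kcal: 7.7
    composite_log_sigma: 0.64
    drink_fraction: 0.05
    red_light_prob: {fat: 0.15, satfat: 0.12, sugar: 0.15, salt: 0.20}
    energy_remainder_median: {food: 100.0, drink: 35.0}
    zero_prob_multiplier: 1.0
    zero_energy: 0
  UPF:
    n: 1650
    composite_median_100kcal: 5.8
    composite_log_sigma: 0.85
    drink_fraction: 0.18
    red_light_prob: {fat: 0.22, satfat: 0.18, sugar: 0.28, salt: 0.22}
    energy_remainder_median: {food: 120.0, drink: 35.0}
    zero_prob_multiplier: 1.2
    zero_energy: 5
shared:
  macro_log_sigma: {fat: 1.2, satfat: 1.2, sugar: 1.0, salt: 0.9}
  energy_log_sigma: 0.7
  latent_macro_rho: 0.55
  latent_energy_rho: 0.55
  latent_micronutrient_rho: -0.40
  dirichlet_concentration: 4.0
  zero_content_prob:
    vitamin_d: 0.45
    vitamin_b12: 0.20
    vitamin_c: 0.25
    vitamin_a: 0.15
    iodine: 0.08
    selenium: 0.05
    folate: 0.03
    default: 0.02
  missing_selenium_upf: 2
  n_non_nova: 0
  n_unmatched: 0
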