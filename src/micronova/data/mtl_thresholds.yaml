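# Multiple-traffic-light (MTL) front-of-package cut-offs, g per 100 g.
#
# Defaults follow the UK FSA/DoH 2016 front-of-pack nutrition labelling
# guidance. "amber" is the upper bound of the green band (value <= amber
# is green); "red" is the upper bound of the amber band (value > red is
# red). Drinks use the lower drink cut-offs, with 100 ml treated as
# equivalent to 100 g. The per-portion red override for large portions is
# intentionally not represented: classification here is strictly per 100 g.
food:
  fat: {amber: 3.0, red: 17.5}
  satfat: {amber: 1.5, red: 5.0}
  sugar: {amber: 5.0, red: 22.5}
  salt: {amber: 0.3, red: 1.5}
drink:
  fat: {amber: 1.5, red: 8.75}
  satfat: {amber: 0.75, red: 2.5}
  sugar: {amber: 2.5, red: 11.25}
  salt: {amber: 0.3, red: 0.75}
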