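# Reference nutrient intakes, UK females aged 19-64 years.
#
# Sources: UK COMA Dietary Reference Values (1991) as carried in current UK
# government guidance, with vitamin D from SACN (2016). Iron uses the
# 19-49 y value of 14.8 mg/d (the 50-64 y recommendation is 8.7 mg/d).
# Every value here is configuration: override with your own file to use
# different reference intakes. Units are per day and must match the
# package's canonical unit registry.
#
# Vitamin E deliberately has no entry: it has an NHS reference value but no
# UK government RNI, and it is excluded from all composite scores.
sex: female
rni:
  vitamin_a: {value: 600.0, unit: ug}
  vitamin_d: {value: 10.0, unit: ug}
  vitamin_c: {value: 40.0, unit: mg}
  thiamin: {value: 0.8, unit: mg}
  riboflavin: {value: 1.1, unit: mg}
  niacin_equivalent: {value: 13.2, unit: mg}
  vitamin_b6: {value: 1.2, unit: mg}
  vitamin_b12: {value: 1.5, unit: ug}
  folate: {value: 200.0, unit: ug}
  potassium: {value: 3500.0, unit: mg}
  calcium: {value: 700.0, unit: mg}
  magnesium: {value: 270.0, unit: mg}
  phosphorus: {value: 550.0, unit: mg}
  iron: {value: 14.8, unit: mg}
  copper: {value: 1.2, unit: mg}
  zinc: {value: 7.0, unit: mg}
  sodium: {value: 1600.0, unit: mg}
  chloride: {value: 2500.0, unit: mg}
  iodine: {value: 140.0, unit: ug}
  selenium: {value: 60.0, unit: ug}
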