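# Reference nutrient intakes, UK males aged 19-64 years.
#
# Sources: UK COMA Dietary Reference Values (1991) as carried in current UK
# government guidance, with vitamin D from SACN (2016). All values are
# configuration and overridable; units are per day in canonical units.
sex: male
rni:
  vitamin_a: {value: 700.0, unit: ug}
  vitamin_d: {value: 10.0, unit: ug}
  vitamin_c: {value: 40.0, unit: mg}
  thiamin: {value: 1.0, unit: mg}
  riboflavin: {value: 1.3, unit: mg}
  niacin_equivalent: {value: 16.5, unit: mg}
  vitamin_b6: {value: 1.4, unit: mg}
  vitamin_b12: {value: 1.5, unit: ug}
  folate: {value: 200.0, unit: ug}
  potassium: {value: 3500.0, unit: mg}
  calcium: {value: 700.0, unit: mg}
  magnesium: {value: 300.0, unit: mg}
  phosphorus: {value: 550.0, unit: mg}
  iron: {value: 8.7, unit: mg}
  copper: {value: 1.2, unit: mg}
  zinc: {value: 9.5, unit: mg}
  sodium: {value: 1600.0, unit: mg}
  chloride: {value: 2500.0, unit: mg}
  iodine: {value: 140.0, unit: ug}
  selenium: {value: 75.0, unit: ug}
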