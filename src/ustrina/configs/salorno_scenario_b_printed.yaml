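# Residual-deposit scenario following the literal subtraction 500 - 157 = 343 g
# for the subadult class; inconsistent with the published budget totals, kept
# so the discrepancy stays visible on the artifact surface.
label: Salorno hypothesis B (residual; literal subadult term 500-157=343 g)
mode: residual
classes:
- name: adult_male
  expected_mass_g: 2500.0
  collected_mass_g: 1695.0
  residual_override_g: null
  ratio: 1
- name: adult_female
  expected_mass_g: 1800.0
  collected_mass_g: 1443.0
  residual_override_g: null
  ratio: 1
- name: subadult
  expected_mass_g: 500.0
  collected_mass_g: 157.0
  residual_override_g: null
  ratio: 2
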