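# Residual-deposit scenario with the subadult per-capita residual set to the
# Frattesina subadult urn average (157 g) via an explicit override: the only
# reading that reproduces the published budget (63,468 g, MNI 172).
label: Salorno hypothesis B (residual; subadult residual 157 g, reproduces published totals)
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
  residual_override_g: 157.0
  ratio: 2
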