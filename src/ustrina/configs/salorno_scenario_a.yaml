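label: Salorno hypothesis A (primary deposition)
mode: primary
classes:
- name: adult_male
  expected_mass_g: 2500.0
  collected_mass_g: 0.0
  residual_override_g: null
  ratio: 1
- name: adult_female
  expected_mass_g: 1800.0
  collected_mass_g: 0.0
  residual_override_g: null
  ratio: 1
- name: subadult
  expected_mass_g: 500.0
  collected_mass_g: 0.0
  residual_override_g: null
  ratio: 2
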