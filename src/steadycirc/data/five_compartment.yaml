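# Bundled five-compartment reference circulation (normal state).
# Identical in content to steadycirc.build_reference_model(); see the
# package docs for parameter meanings and units (L, mmHg, L/min).
format: steadycirc-model/1
heart_right:
  K: 13.5
  alpha: 55.2
  beta: 0.87
  P_ext: -4.0
heart_left:
  K: 13.5
  alpha: 23.1
  beta: 0.326
  P_ext: -4.0
compartments:
- id: right_atrium
  circuit: right_atrium
  C: 0.012
  V0n: 0.102
  P_ext: -4.0
- id: lungs
  circuit: pulmonary
  C: 0.015
  V0n: 0.29
  P_ext: -4.0
  RA: 0.6
  RV: 1.2
- id: left_atrium
  circuit: left_atrium
  C: 0.012
  V0n: 0.102
  P_ext: -4.0
- id: viscera
  circuit: systemic
  C: 0.13
  V0n: 1.38
  P_ext: -4.0
  RA: 36.8
  RV: 3.2
- id: periphery
  circuit: systemic
  C: 0.04
  V0n: 0.6
  P_ext: 0.0
  RA: 38.4
  RV: 1.6
topology:
  pulmonary: lungs
  systemic:
    parallel:
    - viscera
    - periphery
volumes:
  BV: 5.0
  V0: 0.452
pressure_groups:
  P_e:
    compartments:
    - right_atrium
    - lungs
    - left_atrium
    include_heart: true
  P_a:
    compartments:
    - viscera
    include_heart: false
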