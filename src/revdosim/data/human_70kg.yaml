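# Reference-human physiology for the lumped-compartment PBPK model.
# All flows are PLASMA flows (blood flow x (1 - hematocrit)); the liver
# tissue block's flow is the hepatic ARTERY supply — total liver perfusion
# is hepatic artery + gut (portal) outflow.  Values are editable
# configuration, not ground truth; every run logs the physiology used.
species: human
body_weight_kg: 70.0
tissues:
  gut:
    volume_L: 1.65
    flow_L_per_h: 35.0
  liver:
    volume_L: 1.82
    flow_L_per_h: 12.5
  kidney:
    volume_L: 0.31
    flow_L_per_h: 36.5
  rest:
    volume_L: 61.4
    flow_L_per_h: 107.0
venous_plasma_volume_L: 2.25
arterial_plasma_volume_L: 0.75
cardiac_plasma_flow_L_per_h: 191.0
gfr_L_per_h: 6.7
hepatocellularity_1e6_per_g: 110.0
liver_mass_g: 1820.0
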