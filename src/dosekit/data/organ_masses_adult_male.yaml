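# Reference adult-male organ masses (grams) for the hermaphrodite adult
# phantom used by classic internal-dosimetry software (Cristy-Eckerman
# adult, ~73 kg total body). Keys are the biodistribution organ vocabulary;
# composite entries: "large intestine" = upper + lower large intestine wall,
# "bone" = cortical + trabecular bone, "bone marrow" = red (active) marrow,
# "blood" = total blood pool (~5.3 L at unit density).
provenance: >
  Cristy-Eckerman adult phantom organ masses as distributed with classic
  MIRD-schema dosimetry software; composite and blood entries documented in
  the header comment. Not taken from the study being reproduced, which does
  not list organ masses.
masses_g:
  heart: 316.0          # heart wall
  lung: 1000.0
  liver: 1910.0
  stomach: 158.0        # stomach wall
  small intestine: 677.0
  large intestine: 387.0   # ULI wall 220 + LLI wall 167
  spleen: 183.0
  pancreas: 94.3
  kidney: 299.0
  bone: 5000.0          # cortical 4000 + trabecular 1000
  muscle: 28000.0
  bone marrow: 1120.0   # red marrow
  brain: 1420.0
  blood: 5300.0
  # additional human target organs (no mouse measurement; photon bath targets)
  adrenals: 16.3
  thyroid: 20.7
  thymus: 20.9
  testes: 39.1
  ovaries: 8.71
  uterus: 79.0
  urinary bladder wall: 47.6
  gallbladder wall: 10.5
  skin: 3010.0
  breasts: 351.0
  total body: 73000.0
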