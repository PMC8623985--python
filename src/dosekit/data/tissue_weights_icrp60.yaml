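# ICRP Publication 60 tissue weighting factors w_T (the set used by classic
# internal-dosimetry software for effective dose). Keys map ICRP tissues to
# the biodistribution organ vocabulary where possible; tissues with no
# computed organ dose (esophagus, bladder, breast in a mouse panel) receive
# zero dose with a logged warning. "remainder" is applied to the mean dose
# of computed organs that carry no explicit weight.
provenance: >
  ICRP 60 (1991) tissue weighting factors; sum over tissues = 1.
weights:
  gonads: 0.20
  bone marrow: 0.12       # red marrow
  large intestine: 0.12   # colon
  lung: 0.12
  stomach: 0.12
  urinary bladder wall: 0.05
  breasts: 0.05
  liver: 0.05
  esophagus: 0.05
  thyroid: 0.05
  skin: 0.01
  bone: 0.01              # bone surface
  remainder: 0.05
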