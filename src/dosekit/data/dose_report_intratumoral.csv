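target_organ,absorbed_dose
adrenals,0.00492
brain,0.00234
breasts,0.0015
gallbladder wall,0.00743
lli wall,0.00506
small intestine,0.00562
stomach wall,0.00717
uli wall,0.00252
heart wall,0.0222
kidneys,0.135
liver,0.329
lungs,0.0261
muscle,0.00353
ovaries,0.00148
pancreas,0.0118
red marrow,0.00213
skin,0.00125
spleen,0.138
testes,0.000993
thymus,0.00164
thyroid,0.00122
urinary bladder wall,0.00114
uterus,0.00138
tumor_sphere,3.55
total body,0.0169
effective dose,0.0251
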