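target_organ,absorbed_dose
adrenals,0.0906
brain,0.00386
breasts,0.0709
gallbladder wall,0.108
lli wall,0.0777
small intestine,0.0876
stomach wall,0.0814
uli wall,0.0802
heart wall,0.0214
kidneys,0.16
liver,1.97
lungs,0.0637
muscle,0.0114
ovaries,0.074
pancreas,0.0501
red marrow,0.0571
skin,0.0683
spleen,1.37
testes,0.0695
thymus,0.0719
thyroid,0.0703
urinary bladder wall,0.0723
uterus,0.0743
tumor_sphere,0.0382
total body,0.131
effective dose,0.171
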