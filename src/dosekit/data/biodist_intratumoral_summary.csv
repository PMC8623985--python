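organ,time_h,mean_pct_id_per_g,sd_pct_id_per_g
blood,4.0,5.43,3.78
blood,24.0,0.16,0.03
blood,48.0,0.21,0.07
blood,72.0,0.15,0.02
heart,4.0,1.14,0.65
heart,24.0,0.27,0.13
heart,48.0,0.23,0.05
heart,72.0,0.17,0.09
lung,4.0,2.59,0.95
lung,24.0,0.81,0.44
lung,48.0,0.62,0.33
lung,72.0,0.54,0.27
liver,4.0,8.91,4.5
liver,24.0,17.68,6.47
liver,48.0,10.43,4.01
liver,72.0,7.85,5.02
stomach,4.0,0.59,0.1
stomach,24.0,0.36,0.07
stomach,48.0,0.39,0.1
stomach,72.0,0.31,0.02
small intestine,4.0,0.81,0.25
small intestine,24.0,0.61,0.29
small intestine,48.0,0.74,0.38
small intestine,72.0,0.24,0.03
large intestine,4.0,0.51,0.17
large intestine,24.0,0.2,0.06
large intestine,48.0,0.25,0.09
large intestine,72.0,0.15,0.07
spleen,4.0,5.99,1.34
spleen,24.0,8.49,2.74
spleen,48.0,4.85,2.77
spleen,72.0,2.53,2.11
pancreas,4.0,0.65,0.25
pancreas,24.0,0.12,0.05
pancreas,48.0,0.13,0.04
pancreas,72.0,0.14,0.03
kidney,4.0,8.97,1.79
kidney,24.0,7.04,2.07
kidney,48.0,4.31,0.79
kidney,72.0,4.23,1.56
bone,4.0,0.65,0.09
bone,24.0,0.88,0.06
bone,48.0,1.74,0.41
bone,72.0,2.2,0.89
muscle,4.0,0.28,0.14
muscle,24.0,0.07,0.1
muscle,48.0,0.1,0.05
muscle,72.0,0.04,0.05
tumor,4.0,125.09,27.26
tumor,24.0,120.08,51.32
tumor,48.0,35.62,6.85
tumor,72.0,61.44,14.81
bone marrow,4.0,2.12,1.35
bone marrow,24.0,0.55,1.01
bone marrow,48.0,2.15,0.86
bone marrow,72.0,0.0,0.0
brain,4.0,0.16,0.08
brain,24.0,0.02,0.03
brain,48.0,0.02,0.01
brain,72.0,0.03,0.04
urine,4.0,183.23,81.08
urine,24.0,11.41,10.71
urine,48.0,2.04,1.1
urine,72.0,2.49,2.87
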