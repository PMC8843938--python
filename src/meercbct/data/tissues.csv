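name,h_mass_fraction,o_mass_fraction,nominal_red
water,0.1119,0.8881,1.000
adipose,0.114,0.278,0.951
muscle_skeletal,0.102,0.710,1.040
liver,0.102,0.716,1.050
blood_whole,0.102,0.745,1.050
brain,0.107,0.712,1.035
skin,0.100,0.645,1.085
lung_inflated,0.103,0.749,0.258
breast,0.106,0.527,0.976
kidney,0.103,0.724,1.041
spleen,0.103,0.741,1.054
pancreas,0.106,0.694,1.031
heart,0.104,0.718,1.045
thyroid,0.104,0.745,1.041
gi_tract,0.106,0.751,1.024
testis,0.106,0.766,1.038
ovary,0.105,0.768,1.046
eye_lens,0.096,0.646,1.063
cartilage,0.096,0.744,1.083
soft_tissue_avg,0.101,0.762,1.043
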